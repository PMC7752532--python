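# Advertising keywords: a post containing any of these (normalized
# substring match) is flagged as an advertisement and excluded from
# all counting.
detoxification
antioxidant therapy
enzyme therapy
free consultation
special promotion
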