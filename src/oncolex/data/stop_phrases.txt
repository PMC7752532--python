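# Stop phrases: longer phrases in which a cancer keyword loses its
# cancer meaning. Occurrences are masked in place before concept
# matching. Format: phrase TAB note.
agseong virus	computer virus, not a malignant tumour
agseong code	malicious software, not a malignant tumour
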