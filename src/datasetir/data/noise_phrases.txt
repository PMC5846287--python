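# Common non-informative phrases stripped from raw topics before the
# stoplist is applied. Multi-word entries are matched as whole phrases,
# longest first, case-insensitively.
find
search for
related to
data
datasets
dataset
studies
study
all
any
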