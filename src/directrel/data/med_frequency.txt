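# Medication-frequency time expressions (post-processing filter seed
# list); one surface form per line, matched case-insensitively against
# the full time-expression text.
bid
tid
qid
qd
qhs
qod
prn
q2h
q4h
q6h
q8h
q12h
daily
twice daily
three times daily
once daily
every morning
every night
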