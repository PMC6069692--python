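# Type-preserving phrase templates, one per line.
# The single [..] placeholder names the required mention class.
the first course of [Event-Treatment]
episodes of [Event-Problem]
an episode of [Event-Problem]
the time of [Time-Date]
period of [Time-Duration]
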