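class,Not Present,Present
Not Present,32,8
Present,6,74
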