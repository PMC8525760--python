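class,Not Present,Moderately Present,Obviously Present
Not Present,44,4,2
Moderately Present,11,26,2
Obviously Present,3,4,6
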