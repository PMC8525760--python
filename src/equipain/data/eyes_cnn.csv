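class,Not Present,Moderately Present,Obviously Present
Not Present,38,2,7
Moderately Present,16,27,5
Obviously Present,8,11,28
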