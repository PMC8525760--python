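class,Not Present,Moderately Present,Obviously Present
Not Present,32,7,1
Moderately Present,7,27,6
Obviously Present,0,8,32
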