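class,Not Present,Moderately Present,Obviously Present
Not Present,198,0,1
Moderately Present,8,11,1
Obviously Present,11,2,5
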