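chain,resnum,generic
A,100,2x64
A,119,3x28
A,120,3x29
A,121,3x32
A,122,3x33
A,125,3x36
A,170,4x56
A,171,4x57
A,174,4x60
A,175,4x61
A,185,45x50
A,186,45x51
A,187,45x52
A,188,45x53
A,194,5x36
A,197,5x39
A,198,5x40
A,201,5x43
A,202,5x44
A,204,5x46
A,241,6x48
A,244,6x51
A,245,6x52
A,248,6x55
A,270,7x38
A,274,7x42
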