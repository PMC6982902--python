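parameter,method,participant,value_mm
E1,1,1,63
E1,1,2,102
E1,1,3,80
E1,1,4,79
E1,1,5,57
E1,1,6,73
E1,1,7,57
E1,1,8,75
E1,1,9,56
E1,2,1,137
E1,2,2,87
E1,2,3,102
E1,2,4,160
E1,2,5,72
E1,2,6,77
E1,2,7,69
E1,2,8,96
E1,2,9,51
E2,1,1,50
E2,1,2,109
E2,1,3,80
E2,1,4,81
E2,1,5,41
E2,1,6,79
E2,1,7,63
E2,1,8,67
E2,1,9,52
E2,2,1,129
E2,2,2,99
E2,2,3,131
E2,2,4,156
E2,2,5,54
E2,2,6,79
E2,2,7,65
E2,2,8,96
E2,2,9,54
E3,1,1,16
E3,1,2,92
E3,1,3,44
E3,1,4,59
E3,1,5,11
E3,1,6,64
E3,1,7,45
E3,1,8,45
E3,1,9,22
E3,2,1,104
E3,2,2,74
E3,2,3,93
E3,2,4,122
E3,2,5,41
E3,2,6,44
E3,2,7,40
E3,2,8,74
E3,2,9,40
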