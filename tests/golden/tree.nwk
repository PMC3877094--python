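(((BL_01:0.0045751,BL_02:0.0045751):0.0103607,BL_03:0.0149358):0.232922,(((D7_01:0.00290568,D7_02:0.00290568):0.00310987,D7_03:0.00601555):0.0189164,((SLE_01:0.00289342,SLE_02:0.00289342):0.000915211,SLE_03:0.00380863):0.0211233):0.222926);
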