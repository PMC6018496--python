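pair,calculated_mm,actual_mm,printed_relative_error_pct
1-2,301,291,3.44
1-3,452,445,1.57
1-4,345,340,1.47
1-5,275,269,1.56
2-3,260,256,1.56
2-4,409,403,1.49
2-5,511,491,2.04
3-4,310,302,2.65
3-5,545,529,3.02
4-5,266,260,2.31
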