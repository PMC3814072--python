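group,AML,DLCL,BC
AML filtered genes,23248,5741,17769
DLCL filtered genes,2470,10347,6180
BC filtered genes,10787,4015,77223
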