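name,mw_da,volume_ml
carbonic_anhydrase,29000,2.003
BSA,66000,1.802
alcohol_dehydrogenase,150000,1.607
beta_amylase,200000,1.535
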