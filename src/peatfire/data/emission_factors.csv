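fire_type,ef_oc,ef_bc
peat,6.02,0.04
deforestation,4.71,0.52
agricultural,2.30,0.75
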