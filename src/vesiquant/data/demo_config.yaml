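# Demo configuration: full pipeline on the desk-scale phantom.
# The outer-edge erosion is scaled to the miniaturized phantom anatomy
# (the full-scale default of 500 um would consume the whole scaled wall).
seed: 0
erosion_um: 25.0
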