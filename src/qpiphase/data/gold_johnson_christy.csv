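wavelength_nm,n,k
495.9368,0.62,2.081
520.9420,0.43,2.455
548.6027,0.29,2.863
579.3654,0.21,2.897
616.8368,0.13,3.272
659.4904,0.14,3.697
704.4556,0.13,4.103
755.9999,0.14,4.542
821.0874,0.16,5.083
891.9726,0.17,5.663
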