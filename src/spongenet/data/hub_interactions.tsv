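source	target	evidence
circRNA04655	miR-669f-5p	database
circRNA00723	miR-669f-5p	database
circRNA00723	miR-466i-5p	database
circRNA03723	miR-466i-5p	database
circRNA00747	miR-6240	database
circRNA01891	miR-3470b	database
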