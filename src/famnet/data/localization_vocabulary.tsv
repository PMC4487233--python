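term	compartment
extracellular	secreted
extracellular region	secreted
extracellular space	secreted
secreted	secreted
extracellular matrix	secreted
plasma membrane	membrane
membrane	membrane
integral to membrane	membrane
integral component of membrane	membrane
cell surface	membrane
cytoplasm	cytoplasm
cytosol	cytoplasm
cytoskeleton	cytoplasm
mitochondrion	cytoplasm
endoplasmic reticulum	cytoplasm
golgi apparatus	cytoplasm
ribosome	cytoplasm
endosome	cytoplasm
lysosome	cytoplasm
peroxisome	cytoplasm
nucleus	nucleus
nucleoplasm	nucleus
nucleolus	nucleus
chromatin	nucleus
chromosome	nucleus
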