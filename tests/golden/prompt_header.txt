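Identify cell types of human prostate cells using the following markers.
Identify one cell type for each row. Only provide the cell type name.
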