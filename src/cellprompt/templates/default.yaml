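# Prompt template registry. The "default" set pins the canonical wording so
# live-model experiments stay comparable; alternative sets can be added
# without code changes.
annotation_header: |-
  Identify cell types of {subject} cells using the following markers.
  Identify one cell type for each row. Only provide the cell type name.
mixture_clause: "Some could be a mixture of multiple cell types."
unknown_clause: "Some could be unknown cell types."
refinement: "Be more specific"
vector_conversion: |-
  Use "','" to concatenate all results into a single sentence.
  Put "c('" in front of the sentence and "')" after the sentence
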