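# Built-in effector definitions. Users can override or extend these with
# their own YAML file (load_effectors); any 5' or 3' IUPAC motif is allowed.
#
# cut_offset: nt from the motif-proximal protospacer boundary to the
# (blunt-collapsed) cut site. Null = effector does not cut DNA.
cas9:
  spacer_len: 20
  motif: NGG
  motif_side: 3prime
  target_class: DNA
  cut_offset: 3
cas12a:
  spacer_len: 23
  motif: TTTV
  motif_side: 5prime
  target_class: DNA
  cut_offset: 18
casx:
  spacer_len: 20
  motif: TTCN
  motif_side: 5prime
  target_class: DNA
  cut_offset: 18
cas13a:
  spacer_len: 28
  motif: H
  motif_side: 3prime
  target_class: RNA
  cut_offset: null
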