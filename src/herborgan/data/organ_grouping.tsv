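CD33+ myeloid cells	bone marrow
CD34+ hematopoietic stem cells	bone marrow
721 B lymphoblasts	bone marrow
CD14+ monocytes	whole blood
CD56+ NK cells	whole blood
whole blood	whole blood
BDCA4+ dendritic cells	lymphoid tissue
Lymphoma burkitts (Raji)	lymphoid tissue
CD19+ B cells	lymphoid tissue
CD4+ T cells	lymphoid tissue
prostate	prostate
smooth muscle	smooth muscle
cardiac myocytes	cardiac myocytes
thyroid	thyroid
lung	lung
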