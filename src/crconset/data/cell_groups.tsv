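cell_type	group
aDC	myeloid
Adipocytes	other
Astrocytes	other
B-cells	lymphoid
Basophils	myeloid
CD4+ memory T-cells	lymphoid
CD4+ naive T-cells	lymphoid
CD4+ T-cells	lymphoid
CD4+ Tcm	lymphoid
CD4+ Tem	lymphoid
CD8+ naive T-cells	lymphoid
CD8+ T-cells	lymphoid
CD8+ Tcm	lymphoid
CD8+ Tem	lymphoid
cDC	myeloid
Chondrocytes	other
Class-switched memory B-cells	lymphoid
CLP	lymphoid
CMP	myeloid
DC	myeloid
Endothelial cells	other
Eosinophils	myeloid
Epithelial cells	other
Erythrocytes	myeloid
Fibroblasts	other
GMP	myeloid
Hepatocytes	other
HSC	other
iDC	myeloid
Keratinocytes	other
ly Endothelial cells	other
Macrophages	myeloid
Macrophages M1	myeloid
Macrophages M2	myeloid
Mast cells	myeloid
Megakaryocytes	myeloid
Melanocytes	other
Memory B-cells	lymphoid
MEP	myeloid
Mesangial cells	other
Monocytes	myeloid
MPP	other
MSC	other
mv Endothelial cells	other
Myocytes	other
naive B-cells	lymphoid
Neurons	other
Neutrophils	myeloid
NK cells	lymphoid
NKT	lymphoid
Osteoblast	other
pDC	myeloid
Pericytes	other
Plasma cells	lymphoid
Platelets	myeloid
pro B-cells	lymphoid
Preadipocytes	other
Sebocytes	other
Skeletal muscle	other
Smooth muscle	other
Tgd cells	lymphoid
Th1 cells	lymphoid
Th2 cells	lymphoid
Tregs	lymphoid
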