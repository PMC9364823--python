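cell_type	gene
macrophages	Cd44
macrophages	Lyz2
macrophages	C1qa
monocytes	Ly6c2
monocytes	Ms4a6c
monocytes	Csf1r
monocytes	F13a1
granulocytes	Mpo
T_NK_cells	Cd3g
T_NK_cells	Gzma
T_NK_cells	Nkg7
T_NK_cells	Klre1
B_cells	Cd79a
B_cells	Cd79b
B_cells	Ighm
B_cells	Igkc
dendritic_cells	Ccl17
dendritic_cells	H2-Eb1
dendritic_cells	Cd209a
dendritic_cells	Cd74
endothelial_cells	Cldn5
endothelial_cells	Kdr
endothelial_cells	Cdh5
endothelial_cells	Pecam1
endothelial_cells	Eng
fibroblasts	Dcn
fibroblasts	Gsn
fibroblasts	Col1a2
fibroblasts	Col3a1
fibroblasts	Col1a1
fibroblasts	Mgp
fibroblasts	Gpx3
smooth_muscle_cells	Acta2
smooth_muscle_cells	Myl9
smooth_muscle_cells	Mustn1
epithelial_cells	Krt18
epithelial_cells	Krt8
epithelial_cells	Foxj1
epithelial_cells	Sntn
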