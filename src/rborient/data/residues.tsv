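# Residue neutron scattering parameters, version 1
# b_h: summed coherent scattering length, all H as 1H, Angstrom
# b_d: same with the n_labile exchangeable H as 2H, Angstrom
# volume: empirical residue volume, Angstrom^3; mass: average residue mass, Da
# formula: residue-unit composition C/H/N/O/S (side chains in their pH~7 charge state)
code	b_h	b_d	volume	n_labile	mass	formula
ALA	1.640600e-04	2.681600e-04	88.6	1	71.08	C3H5N1O1
ARG	3.451200e-04	9.697200e-04	173.4	6	156.19	C6H13N4O1
ASN	3.447600e-04	6.570600e-04	114.1	3	114.1	C4H6N2O2
ASP	3.839700e-04	4.880700e-04	111.1	1	115.09	C4H4N1O3
CYS	1.925300e-04	4.007300e-04	108.5	2	103.14	C3H5N1O1S1
GLN	3.364400e-04	6.487400e-04	143.8	3	128.13	C5H8N2O2
GLU	3.756500e-04	4.797500e-04	138.4	1	129.12	C5H6N1O3
GLY	1.723800e-04	2.764800e-04	60.1	1	57.05	C2H3N1O1
HIS	4.758600e-04	6.840600e-04	153.2	2	137.14	C6H7N3O1
ILE	1.391000e-04	2.432000e-04	166.7	1	113.16	C6H11N1O1
LEU	1.391000e-04	2.432000e-04	166.7	1	113.16	C6H11N1O1
LYS	1.579200e-04	5.743200e-04	168.6	4	128.17	C6H13N2O1
MET	1.758900e-04	2.799900e-04	162.9	1	131.19	C5H9N1O1S1
PHE	4.132600e-04	5.173600e-04	189.9	1	147.18	C9H9N1O1
PRO	2.222000e-04	2.222000e-04	112.7	0	97.12	C5H7N1O1
SER	2.220900e-04	4.302900e-04	89.0	2	87.08	C3H5N1O2
THR	2.137700e-04	4.219700e-04	116.1	2	101.1	C4H7N1O2
TRP	6.023900e-04	8.105900e-04	227.8	2	186.21	C11H10N2O1
TYR	4.712900e-04	6.794900e-04	193.6	2	163.18	C9H9N1O2
VAL	1.474200e-04	2.515200e-04	140.0	1	99.13	C5H9N1O1
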