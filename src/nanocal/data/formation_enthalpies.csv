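name,state,formula,charge,dHf25_kJ_per_mol,cp_J_per_mol_K,source
H2O,liquid,H2O,0,-285.830,75.29,CODATA
H+,aqueous,H,1,0.0,0.0,convention (zero for the aqueous proton)
e-,aqueous,,-1,0.0,0.0,convention (zero for the electron)
O2,aqueous,O2,0,-12.13,,SUPCRT slop-file value (-2900 cal/mol)
H2,aqueous,H2,0,-4.18,,SUPCRT slop-file value (-1000 cal/mol)
N2,aqueous,N2,0,-10.44,,SUPCRT slop-file value (-2495 cal/mol)
CO2,aqueous,CO2,0,-413.79,,SUPCRT slop-file value (-98900 cal/mol)
SO4-2,aqueous,SO4,-2,-909.27,-293.0,CODATA; cp partial molal estimate
HS-,aqueous,HS,-1,-16.3,-93.0,CODATA; cp partial molal estimate
NO3-,aqueous,NO3,-1,-206.85,-86.6,CODATA; cp partial molal estimate
NH4+,aqueous,NH4,1,-133.26,79.9,Shock-Helgeson ion compilation (-31850 cal/mol)
acetate,aqueous,C2H3O2,-1,-486.01,,CODATA (CH3COO-)
formate,aqueous,CHO2,-1,-425.55,,CODATA (HCOO-)
glycine,aqueous,C2H5NO2,0,-513.99,,aqueous amino-acid compilation (crystal dHf + dissolution)
alanine,aqueous,C3H7NO2,0,-552.7,,aqueous amino-acid compilation (crystal dHf + dissolution)
valine,aqueous,C5H11NO2,0,-613.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
leucine,aqueous,C6H13NO2,0,-632.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
isoleucine,aqueous,C6H13NO2,0,-631.5,,aqueous amino-acid compilation (crystal dHf + dissolution)
proline,aqueous,C5H9NO2,0,-517.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
phenylalanine,aqueous,C9H11NO2,0,-456.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
tryptophan,aqueous,C11H12N2O2,0,-409.8,,aqueous amino-acid compilation (crystal dHf + dissolution)
methionine,aqueous,C5H11NO2S,0,-567.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
serine,aqueous,C3H7NO3,0,-721.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
threonine,aqueous,C4H9NO3,0,-796.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
cysteine,aqueous,C3H7NO2S,0,-526.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
asparagine,aqueous,C4H8N2O3,0,-766.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
glutamine,aqueous,C5H10N2O3,0,-811.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
aspartate,aqueous,C4H7NO4,0,-947.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
glutamate,aqueous,C5H9NO4,0,-982.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
lysine,aqueous,C6H14N2O2,0,-684.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
arginine,aqueous,C6H14N4O2,0,-623.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
histidine,aqueous,C6H9N3O2,0,-453.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
tyrosine,aqueous,C9H11NO3,0,-661.0,,aqueous amino-acid compilation (crystal dHf + dissolution)
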