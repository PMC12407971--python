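name,abbreviation,fmri_only
Precentral gyrus,PreCG,0
Superior frontal gyrus (dorsolateral),SFGdor,0
Superior frontal gyrus (orbital),ORBsup,0
Middle frontal gyrus,MFG,0
Middle frontal gyrus (orbital),ORBmid,0
Inferior frontal gyrus (opercular),IFGoperc,0
Inferior frontal gyrus (triangular),IFGtriang,0
Inferior frontal gyrus (orbital),ORBinf,0
Rolandic operculum,ROL,0
Supplementary motor area,SMA,0
Olfactory cortex,OLF,0
Superior frontal gyrus (medial),SFGmed,0
Superior frontal gyrus (medial orbital),ORBsupmed,0
Rectus gyrus,REC,0
Insula,INS,0
Anterior cingulate gyrus,ACG,0
Median cingulate gyrus,MCG,0
Posterior cingulate gyrus,PCG,0
Hippocampus,HIP,0
Parahippocampal gyrus,PHG,0
Amygdala,AMYG,0
Calcarine cortex,CAL,0
Cuneus,CUN,0
Lingual gyrus,LING,0
Superior occipital gyrus,SOG,0
Middle occipital gyrus,MOG,0
Inferior occipital gyrus,IOG,0
Fusiform gyrus,FFG,0
Postcentral gyrus,PoCG,0
Superior parietal gyrus,SPG,0
Inferior parietal gyrus,IPG,0
Supramarginal gyrus,SMG,0
Angular gyrus,ANG,0
Precuneus,PCUN,0
Paracentral lobule,PCL,0
Caudate,CAU,1
Putamen,PUT,1
Pallidum,PAL,1
Thalamus,THA,1
Heschl gyrus,HES,0
Superior temporal gyrus,STG,0
Temporal pole (superior),TPOsup,0
Middle temporal gyrus,MTG,0
Temporal pole (middle),TPOmid,0
Inferior temporal gyrus,ITG,0
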