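name,hemisphere,group,label_id,networks,in_strict_72
entorhinal,left,temporal,1,,1
parahippocampal,left,temporal,2,,1
fusiform,left,temporal,3,,1
superior_temporal,left,temporal,4,,1
middle_temporal,left,temporal,5,DMN,1
inferior_temporal,left,temporal,6,CEN_FPN,1
transverse_temporal,left,temporal,7,,1
temporal_pole,left,temporal,8,,1
superior_frontal,left,frontal,9,,1
rostral_middle_frontal,left,frontal,10,CEN_FPN,1
caudal_middle_frontal,left,frontal,11,,1
pars_opercularis,left,frontal,12,,1
pars_triangularis,left,frontal,13,,1
pars_orbitalis,left,frontal,14,,1
lateral_orbitofrontal,left,frontal,15,CEN_FPN,1
medial_orbitofrontal,left,frontal,16,DMN,1
precentral,left,frontal,17,,1
paracentral,left,frontal,18,,1
frontal_pole,left,frontal,19,,1
postcentral,left,parietal,20,,1
supramarginal,left,parietal,21,,1
superior_parietal,left,parietal,22,,1
inferior_parietal,left,parietal,23,CEN_FPN,1
precuneus,left,parietal,24,DMN,1
lingual,left,occipital,25,,1
pericalcarine,left,occipital,26,,1
cuneus,left,occipital,27,,1
lateral_occipital,left,occipital,28,,1
rostral_anterior_cingulate,left,cingulate,29,SN,1
caudal_anterior_cingulate,left,cingulate,30,CEN_FPN,1
posterior_cingulate,left,cingulate,31,DMN,1
isthmus_cingulate,left,cingulate,32,,1
thalamus,left,basal_ganglia,33,,1
caudate,left,basal_ganglia,34,CEN_FPN,1
putamen,left,basal_ganglia,35,,1
pallidus,left,basal_ganglia,36,,1
insula,left,insula,37,SN,0
angular,left,parietal,38,DMN,0
entorhinal,right,temporal,101,,1
parahippocampal,right,temporal,102,,1
fusiform,right,temporal,103,,1
superior_temporal,right,temporal,104,,1
middle_temporal,right,temporal,105,DMN,1
inferior_temporal,right,temporal,106,CEN_FPN,1
transverse_temporal,right,temporal,107,,1
temporal_pole,right,temporal,108,,1
superior_frontal,right,frontal,109,,1
rostral_middle_frontal,right,frontal,110,CEN_FPN,1
caudal_middle_frontal,right,frontal,111,,1
pars_opercularis,right,frontal,112,,1
pars_triangularis,right,frontal,113,,1
pars_orbitalis,right,frontal,114,,1
lateral_orbitofrontal,right,frontal,115,CEN_FPN,1
medial_orbitofrontal,right,frontal,116,DMN,1
precentral,right,frontal,117,,1
paracentral,right,frontal,118,,1
frontal_pole,right,frontal,119,,1
postcentral,right,parietal,120,,1
supramarginal,right,parietal,121,,1
superior_parietal,right,parietal,122,,1
inferior_parietal,right,parietal,123,CEN_FPN,1
precuneus,right,parietal,124,DMN,1
lingual,right,occipital,125,,1
pericalcarine,right,occipital,126,,1
cuneus,right,occipital,127,,1
lateral_occipital,right,occipital,128,,1
rostral_anterior_cingulate,right,cingulate,129,SN,1
caudal_anterior_cingulate,right,cingulate,130,CEN_FPN,1
posterior_cingulate,right,cingulate,131,DMN,1
isthmus_cingulate,right,cingulate,132,,1
thalamus,right,basal_ganglia,133,,1
caudate,right,basal_ganglia,134,CEN_FPN,1
putamen,right,basal_ganglia,135,,1
pallidus,right,basal_ganglia,136,,1
insula,right,insula,137,SN,0
angular,right,parietal,138,DMN,0
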