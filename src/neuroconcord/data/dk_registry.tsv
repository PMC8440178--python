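region	class
bankssts	cortical
caudalanteriorcingulate	cortical
caudalmiddlefrontal	cortical
cuneus	cortical
entorhinal	cortical
frontalpole	cortical
fusiform	cortical
inferiorparietal	cortical
inferiortemporal	cortical
insula	cortical
isthmuscingulate	cortical
lateraloccipital	cortical
lateralorbitofrontal	cortical
lingual	cortical
medialorbitofrontal	cortical
middletemporal	cortical
paracentral	cortical
parahippocampal	cortical
parsopercularis	cortical
parsorbitalis	cortical
parstriangularis	cortical
pericalcarine	cortical
postcentral	cortical
posteriorcingulate	cortical
precentral	cortical
precuneus	cortical
rostralanteriorcingulate	cortical
rostralmiddlefrontal	cortical
superiorfrontal	cortical
superiorparietal	cortical
superiortemporal	cortical
supramarginal	cortical
temporalpole	cortical
transversetemporal	cortical
thalamus	subcortical
caudate	subcortical
putamen	subcortical
pallidum	subcortical
hippocampus	subcortical
amygdala	subcortical
accumbens	subcortical
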