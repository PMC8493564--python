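name,kind,value,units
glc_ext,environment,10000.0,uM
gln_ext,environment,2000.0,uM
cys2_ext,environment,200.0,uM
cys2_in,concentration,100.0,uM
cys,concentration,100.0,uM
glu,concentration,3000.0,uM
nadph,concentration,0.96,uM
gsh,concentration,3000.0,uM
gssg,concentration,30.0,uM
ros,concentration,0.01,uM
ca,concentration,0.1,uM
pptase_red,concentration,0.0333,uM
tk_phos,concentration,0.045,uM
cystine_uptake,flux,30.0,uM/min
gsh_synthesis,flux,30.0,uM/min
glutamate_production,flux,64.0,uM/min
nadph_ox_anabolism,flux,10.0,uM/min
nadph_regen_glu,flux,5.7,uM/min
gsh_oxidation,flux,100.0,uM/min
gsh_degradation,flux,29.41176470588235,uM/min
nadph_ox_gssg,flux,99.70588235294117,uM/min
nadph_regen_glc,flux,134.00588235294117,uM/min
ros_production_basal,flux,15.0,uM/min
ros_production_glc,flux,10.0,uM/min
ros_production_glu,flux,75.0,uM/min
ros,fold_activation,100.0,fold
ca,fold_activation,1.7,fold
ca,timescale,1.0,1/min or 1/(uM*min)
pptase,timescale,250.0,1/min or 1/(uM*min)
tk,timescale,0.5,1/min or 1/(uM*min)
K_cys2_import,fixed,300.0,model units
K_gln_import,fixed,1000.0,model units
K_glc_import,fixed,3000.0,model units
K_glu_import_ros,fixed,1000.0,model units
f_ros_from_glc,fixed,0.1,model units
f_ros_from_glu,fixed,0.75,model units
K_ros_inhibition,fixed,1.5,model units
n1,fixed,6.0,model units
SLC7A11,fixed,5.0,model units
NADP_total,fixed,1.0,model units
PPTase_total,fixed,0.1,model units
TK_total,fixed,0.1,model units
switch_nadp_import,fixed,0.95,model units
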