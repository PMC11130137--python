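id,label,association,trophic_role,diet
spider_P,spider_P_,obligate,predator,springtail_D;fac_prey_D;fac_mite_D
rove_beetle_P,rove beetle_P_,obligate,predator,springtail_D;fac_prey_D
rove_beetle_SP1,rove beetle_SP1_,obligate,scavenger_predator,nest_food;ant_brood;springtail_D;isopod_D;beetle_D;fac_prey_D;fac_mite_D;fac_mite_P
rove_beetle_SP2,rove beetle_SP2_,obligate,scavenger_predator,nest_food;springtail_D;fac_prey_D;fac_mite_D
rove_beetle_S,rove beetle_S_,obligate,scavenger,nest_food
beetle_D,beetle_D_,obligate,detritivore,nest_food
beetle_B,beetle_B_,obligate,brood_predator,ant_brood
springtail_D,springtail_D_,obligate,detritivore,nest_food
isopod_D,isopod_D_,obligate,detritivore,nest_food
fac_armoured_D,fac armoured_D_,facultative,detritivore,nest_food
fac_pred_P1,fac pred_P1_,facultative,predator,springtail_D;fac_prey_D;fac_mite_D;isopod_D
fac_pred_P2,fac pred_P2_,facultative,predator,springtail_D;fac_prey_D;fac_mite_D
fac_prey_D,fac prey_D_,facultative,detritivore,nest_food
fac_rove_beetle_S,fac rove beetle_S_,facultative,scavenger,nest_food
fac_mite_D,fac mite_D_,facultative,detritivore,nest_food
fac_mite_P,fac mite_P_,facultative,predator,springtail_D;fac_prey_D;fac_mite_D
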