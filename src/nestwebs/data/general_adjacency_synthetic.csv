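consumer,resource
spider_P,springtail_D
spider_P,fac_prey_D
spider_P,fac_mite_D
rove_beetle_P,springtail_D
rove_beetle_P,fac_prey_D
rove_beetle_SP1,nest_food
rove_beetle_SP1,springtail_D
rove_beetle_SP1,fac_prey_D
rove_beetle_SP1,fac_mite_D
rove_beetle_SP1,fac_mite_P
rove_beetle_SP2,nest_food
rove_beetle_SP2,fac_prey_D
rove_beetle_SP2,fac_mite_D
rove_beetle_S,nest_food
beetle_D,nest_food
beetle_B,ant_brood
springtail_D,nest_food
isopod_D,nest_food
fac_armoured_D,nest_food
fac_pred_P1,springtail_D
fac_pred_P1,fac_prey_D
fac_pred_P1,fac_mite_D
fac_pred_P1,isopod_D
fac_pred_P2,springtail_D
fac_pred_P2,fac_prey_D
fac_pred_P2,fac_mite_D
fac_prey_D,nest_food
fac_rove_beetle_S,nest_food
fac_mite_D,nest_food
fac_mite_P,springtail_D
fac_mite_P,fac_prey_D
fac_mite_P,fac_mite_D
rove_beetle_SP1,ant_brood
rove_beetle_SP1,isopod_D
rove_beetle_SP1,beetle_D
rove_beetle_SP2,springtail_D
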