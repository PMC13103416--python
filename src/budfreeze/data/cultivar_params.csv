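cultivar,percentile,param_name,value,source
Cabernet-Sauvignon,10,ch_max_c,-21.0,packaged-defaults
Cabernet-Sauvignon,10,ch_init_c,-7.8,packaged-defaults
Cabernet-Sauvignon,10,acc_rate,0.095,packaged-defaults
Cabernet-Sauvignon,10,acc_temp_max_c,14.0,packaged-defaults
Cabernet-Sauvignon,10,acc_chill_decay,0.10,packaged-defaults
Cabernet-Sauvignon,10,dea_rate,0.2376,packaged-defaults
Cabernet-Sauvignon,10,dea_temp_base_c,4.0,packaged-defaults
Cabernet-Sauvignon,10,pot_chill_half,85.0,packaged-defaults
Cabernet-Sauvignon,10,pot_steepness,0.15,packaged-defaults
Cabernet-Sauvignon,50,ch_max_c,-23.5,packaged-defaults
Cabernet-Sauvignon,50,ch_init_c,-9.0,packaged-defaults
Cabernet-Sauvignon,50,acc_rate,0.10,packaged-defaults
Cabernet-Sauvignon,50,acc_temp_max_c,14.0,packaged-defaults
Cabernet-Sauvignon,50,acc_chill_decay,0.10,packaged-defaults
Cabernet-Sauvignon,50,dea_rate,0.22,packaged-defaults
Cabernet-Sauvignon,50,dea_temp_base_c,4.0,packaged-defaults
Cabernet-Sauvignon,50,pot_chill_half,85.0,packaged-defaults
Cabernet-Sauvignon,50,pot_steepness,0.15,packaged-defaults
Cabernet-Sauvignon,90,ch_max_c,-26.0,packaged-defaults
Cabernet-Sauvignon,90,ch_init_c,-10.2,packaged-defaults
Cabernet-Sauvignon,90,acc_rate,0.105,packaged-defaults
Cabernet-Sauvignon,90,acc_temp_max_c,14.0,packaged-defaults
Cabernet-Sauvignon,90,acc_chill_decay,0.10,packaged-defaults
Cabernet-Sauvignon,90,dea_rate,0.2024,packaged-defaults
Cabernet-Sauvignon,90,dea_temp_base_c,4.0,packaged-defaults
Cabernet-Sauvignon,90,pot_chill_half,85.0,packaged-defaults
Cabernet-Sauvignon,90,pot_steepness,0.15,packaged-defaults
Riesling,10,ch_max_c,-24.0,packaged-defaults
Riesling,10,ch_init_c,-8.7,packaged-defaults
Riesling,10,acc_rate,0.114,packaged-defaults
Riesling,10,acc_temp_max_c,14.0,packaged-defaults
Riesling,10,acc_chill_decay,0.10,packaged-defaults
Riesling,10,dea_rate,0.324,packaged-defaults
Riesling,10,dea_temp_base_c,4.0,packaged-defaults
Riesling,10,pot_chill_half,80.0,packaged-defaults
Riesling,10,pot_steepness,0.15,packaged-defaults
Riesling,50,ch_max_c,-26.5,packaged-defaults
Riesling,50,ch_init_c,-9.9,packaged-defaults
Riesling,50,acc_rate,0.12,packaged-defaults
Riesling,50,acc_temp_max_c,14.0,packaged-defaults
Riesling,50,acc_chill_decay,0.10,packaged-defaults
Riesling,50,dea_rate,0.30,packaged-defaults
Riesling,50,dea_temp_base_c,4.0,packaged-defaults
Riesling,50,pot_chill_half,80.0,packaged-defaults
Riesling,50,pot_steepness,0.15,packaged-defaults
Riesling,90,ch_max_c,-29.0,packaged-defaults
Riesling,90,ch_init_c,-11.1,packaged-defaults
Riesling,90,acc_rate,0.126,packaged-defaults
Riesling,90,acc_temp_max_c,14.0,packaged-defaults
Riesling,90,acc_chill_decay,0.10,packaged-defaults
Riesling,90,dea_rate,0.276,packaged-defaults
Riesling,90,dea_temp_base_c,4.0,packaged-defaults
Riesling,90,pot_chill_half,80.0,packaged-defaults
Riesling,90,pot_steepness,0.15,packaged-defaults
Concord,10,ch_max_c,-27.5,packaged-defaults
Concord,10,ch_init_c,-9.8,packaged-defaults
Concord,10,acc_rate,0.133,packaged-defaults
Concord,10,acc_temp_max_c,14.5,packaged-defaults
Concord,10,acc_chill_decay,0.10,packaged-defaults
Concord,10,dea_rate,0.432,packaged-defaults
Concord,10,dea_temp_base_c,4.0,packaged-defaults
Concord,10,pot_chill_half,75.0,packaged-defaults
Concord,10,pot_steepness,0.16,packaged-defaults
Concord,50,ch_max_c,-30.0,packaged-defaults
Concord,50,ch_init_c,-11.0,packaged-defaults
Concord,50,acc_rate,0.14,packaged-defaults
Concord,50,acc_temp_max_c,14.5,packaged-defaults
Concord,50,acc_chill_decay,0.10,packaged-defaults
Concord,50,dea_rate,0.40,packaged-defaults
Concord,50,dea_temp_base_c,4.0,packaged-defaults
Concord,50,pot_chill_half,75.0,packaged-defaults
Concord,50,pot_steepness,0.16,packaged-defaults
Concord,90,ch_max_c,-32.5,packaged-defaults
Concord,90,ch_init_c,-12.2,packaged-defaults
Concord,90,acc_rate,0.147,packaged-defaults
Concord,90,acc_temp_max_c,14.5,packaged-defaults
Concord,90,acc_chill_decay,0.10,packaged-defaults
Concord,90,dea_rate,0.368,packaged-defaults
Concord,90,dea_temp_base_c,4.0,packaged-defaults
Concord,90,pot_chill_half,75.0,packaged-defaults
Concord,90,pot_steepness,0.16,packaged-defaults
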