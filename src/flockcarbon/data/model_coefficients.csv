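model,term,beta,se,n,r2,alt_beta,note
replacement_females,intercept,-136.7,271,61,0.65,,
replacement_females,present_females,0.42,,,,,
born_offspring,intercept,-112.1,392,61,0.95,,
born_offspring,present_females,1.91,,,,,
culled_offspring,intercept,91.4,326,61,0.87,,
culled_offspring,present_females,0.97,,,,0.98,model-string reading kept; table-of-coefficients prints 0.98
adult_losses,intercept,122.6,189,19,0.80,-122.6,model-string reading kept; table-of-coefficients prints -122.6
adult_losses,present_females,0.40,,,,,
offspring_deaths,intercept,-117.2,377,48,0.59,,
offspring_deaths,present_females,0.55,,,,,
feces_g_dm,intercept,523,59.3,510,0.64,512.7,model-string reading kept; table-of-coefficients prints 512.7
feces_g_dm,omd_pct_over_100,-692.6,,,,-699.1,model-string reading kept
feces_g_dm,dmi_g,0.084,,,,,
feces_g_dm,gp_g,0.57,,,,0.579,
feces_g_dm,ndf_g,0.269,,,,,
urine_ml,intercept,-654.1,529,313,0.56,,
urine_ml,n_intake_g,71.3,,,,,
n_feces_g,intercept,1.30,1.26,510,0.78,,
n_feces_g,n_intake_g,0.24,,,,0.241,
n_urine_g,intercept,1.95,4.06,313,0.64,,
n_urine_g,n_intake_g,0.64,,,,,
n_feces_repl_g,intercept,0.16,0.065,0,0.91,,
n_feces_repl_g,n_per_met_wt,0.3,,,,,
n_urine_repl_g,intercept,-0.0061,0.06,0,0.98,,
n_urine_repl_g,n_per_met_wt,0.31,,,,,
triticale_kg_dm_ha,intercept,-11952,669,59,0.93,-11052,model-string reading kept; table-of-coefficients prints -11052
triticale_kg_dm_ha,height_cm,133.2,,,,,
triticale_kg_dm_ha,days_to_ear,33.9,,,,,
triticale_kg_dm_ha,n_basal_kg_ha,62.9,,,,,
oats_kg_dm_ha,intercept,-2632,1211,35,0.87,2632,model-string reading kept; table-of-coefficients prints +2632
oats_kg_dm_ha,height_cm,112,,,,112.6,
milk_per_lactation_L,intercept,198.3,24.2,0,0.89,,
milk_per_lactation_L,genetic_value,5.3,,,,,
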