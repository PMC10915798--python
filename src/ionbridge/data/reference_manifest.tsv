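system_name	pH	buffer_mM	nacl_mM	run_ns	n_runs
Fab_Phos_7.2	7.2	20	150	200	5
Fc_Phos_7.2	7.2	20	150	200	5
Fab_Phos_7.2-ns	7.2	20	0	200	3
Fc_Phos_7.2-ns	7.2	20	0	200	3
Fab_Cit_6	6.0	20	150	200	5
Fc_Cit_6	6.0	20	150	200	5
Fab_Cit_6-ns	6.0	20	0	200	3
Fc_Cit_6-ns	6.0	20	0	200	3
2Fab_Cit_6	6.0	50	0	200	3
2Fab_Phos_7.2	7.2	50	0	200	3
2Fab_nb_6	6.0	0	90	200	3
2Fab_nb_7.2	7.2	0	50	200	3
2Fc_Cit_6	6.0	50	0	200	3
2Fc_Phos_7.2	7.2	50	0	200	3
2Fc_nb_6	6.0	0	108	200	3
2Fc_nb_7.2	7.2	0	76	200	3
Fab-Fc_Cit_6	6.0	50	0	200	3
Fab-Fc_Phos_7.2	7.2	50	0	200	3
Fab-Fc_nb_6	6.0	0	100	200	3
Fab-Fc_nb_7.2	7.2	0	65	200	3
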