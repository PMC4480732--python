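complex_id	e_int_ele	e_int_vdw	g_sol_nopol	g_sol_ele	neg_t_ds	g_sol_printed	g_ele_printed	g_bind_printed
PIM1-PI003	-41.60	-34.71	-5.54	48.18	-9.8	42.64	6.58	-43.69
PIM2-PI003	-41.83	-37.57	-5.12	55.91	-10.2	50.79	14.08	-38.81
PIM3-PI003	-34.00	-35.85	-5.60	41.75	-8.2	36.15	7.75	-42.12
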