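parameter	unit	group	mean	sem	n
total_cholesterol	mg/dl	normal_control	121.1	3.83	3
total_cholesterol	mg/dl	diabetic_control	194.4	1.21	3
total_cholesterol	mg/dl	metformin_5	163.5	5.67	3
total_cholesterol	mg/dl	probucol_5	144.1	3.20	3
total_cholesterol	mg/dl	mp_5_0.5	147.3	2.54	3
total_cholesterol	mg/dl	mp_2.5_0.5	155.5	3.70	3
total_cholesterol	mg/dl	mp_2.5_0.25	166.1	1.54	3
triglycerides	mg/dl	normal_control	111.9	3.29	3
triglycerides	mg/dl	diabetic_control	278.9	6.30	3
triglycerides	mg/dl	metformin_5	204.6	9.63	3
triglycerides	mg/dl	probucol_5	146.6	7.49	3
triglycerides	mg/dl	mp_5_0.5	132.2	9.25	3
triglycerides	mg/dl	mp_2.5_0.5	175.7	6.04	3
triglycerides	mg/dl	mp_2.5_0.25	193.0	3.09	3
hdl_cholesterol	mg/dl	normal_control	54.83	2.57	3
hdl_cholesterol	mg/dl	diabetic_control	26.14	1.45	3
hdl_cholesterol	mg/dl	metformin_5	39.43	0.60	3
hdl_cholesterol	mg/dl	probucol_5	31.62	0.64	3
hdl_cholesterol	mg/dl	mp_5_0.5	36.84	1.27	3
hdl_cholesterol	mg/dl	mp_2.5_0.5	34.68	0.69	3
hdl_cholesterol	mg/dl	mp_2.5_0.25	35.06	0.73	3
ldl_cholesterol	mg/dl	normal_control	43.90	6.42	3
ldl_cholesterol	mg/dl	diabetic_control	112.5	2.16	3
ldl_cholesterol	mg/dl	metformin_5	80.04	4.90	3
ldl_cholesterol	mg/dl	probucol_5	83.12	3.44	3
ldl_cholesterol	mg/dl	mp_5_0.5	84.00	5.24	3
ldl_cholesterol	mg/dl	mp_2.5_0.5	86.66	5.63	3
ldl_cholesterol	mg/dl	mp_2.5_0.25	92.47	1.70	3
serum_glucose	mg/dl	normal_control	96.49	1.74	3
serum_glucose	mg/dl	diabetic_control	395.4	5.37	3
serum_glucose	mg/dl	metformin_5	188.0	11.41	3
serum_glucose	mg/dl	probucol_5	233.8	7.96	3
serum_glucose	mg/dl	mp_5_0.5	123.2	4.70	3
serum_glucose	mg/dl	mp_2.5_0.5	166.1	13.43	3
serum_glucose	mg/dl	mp_2.5_0.25	190.1	10.71	3
hba1c	ng/ml	normal_control	13.19	0.88	3
hba1c	ng/ml	diabetic_control	33.79	7.68	3
hba1c	ng/ml	metformin_5	22.88	1.66	3
hba1c	ng/ml	probucol_5	25.79	0.92	3
hba1c	ng/ml	mp_5_0.5	17.02	1.07	3
hba1c	ng/ml	mp_2.5_0.5	20.65	1.16	3
hba1c	ng/ml	mp_2.5_0.25	21.61	1.30	3
insulin	uIU/ml	normal_control	16.82	0.85	3
insulin	uIU/ml	diabetic_control	7.78	1.36	3
insulin	uIU/ml	metformin_5	12.01	0.70	3
insulin	uIU/ml	probucol_5	10.41	0.84	3
insulin	uIU/ml	mp_5_0.5	14.73	0.63	3
insulin	uIU/ml	mp_2.5_0.5	13.27	0.88	3
insulin	uIU/ml	mp_2.5_0.25	13.17	0.27	3
tbars	uM	normal_control	5.65	0.30	3
tbars	uM	diabetic_control	8.46	0.99	3
tbars	uM	metformin_5	7.67	0.32	3
tbars	uM	probucol_5	6.64	0.39	3
tbars	uM	mp_5_0.5	5.91	0.25	3
tbars	uM	mp_2.5_0.5	6.77	0.65	3
tbars	uM	mp_2.5_0.25	7.03	0.39	3
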