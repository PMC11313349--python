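scale	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
synthetic_scale_01	0.379	-1.582	0.757	-0.374	-1.963	-0.614	-1.235	-0.873	1.891	0.09	-1.107	-0.655	-1.168	-1.513	1.322	0.827	-0.271	-0.253	-1.879	-0.131
synthetic_scale_02	-1.207	1.046	1.28	1.256	0.537	1.192	0.127	1.078	1.011	2.245	-0.912	-0.429	1.182	1.324	1.531	1.718	0.482	0.202	-0.871	0.299
synthetic_scale_03	0.386	-0.065	0.209	-1.689	1.129	-0.618	-2.424	-0.488	-1.329	0.614	0.255	-1.669	0.878	-0.151	-0.023	-0.59	0.101	-0.931	0.651	-0.25
synthetic_scale_04	-1.02	0.718	-0.41	-0.126	-1.161	0.297	0.666	2.178	0.769	0.584	0.077	-1.851	0.729	-0.116	-1.041	-0.335	1.169	1.977	0.048	0.345
synthetic_scale_05	-0.728	0.074	-0.764	1.084	-0.941	0.447	0.545	-0.275	-0.295	0.557	-1.35	0.231	0.756	-1.023	0.705	-0.353	-0.622	-2.067	-1.242	1.097
synthetic_scale_06	-0.901	1.664	-0.916	-0.988	0.019	-1.715	1.551	0.02	-2.004	-1.768	0.661	1.428	1.409	0.288	0.336	0.684	-1.264	-0.699	-0.344	-0.423
synthetic_scale_07	-0.178	-1.3	0.375	2.959	0.05	0.482	1.197	0.073	0.621	-0.547	-0.322	1.054	-1.515	-0.202	0.774	0.368	-1.314	0.076	0.711	-0.219
synthetic_scale_08	0.839	-0.95	-0.069	-0.096	-0.788	-0.975	-2.046	-1.832	-1.176	-0.612	1.017	-0.14	0.489	0.241	0.046	0.412	0.788	-1.585	-0.478	0.857
synthetic_scale_09	-1.131	-0.802	0.11	0.143	-1.698	-1.598	1.038	-0.762	-0.344	0.881	-1.607	-0.8	1.485	-0.786	-1.378	-0.089	1.552	-0.725	1.454	-0.705
synthetic_scale_10	-0.241	-0.925	0.263	-0.046	0.556	1.758	-1.485	0.997	-0.692	-0.583	0.552	0.031	-0.459	0.049	0.344	1.077	1.523	-1.858	0.568	1.625
synthetic_scale_11	-2.284	2.033	2.268	-0.259	1.279	-0.642	-2.227	2.622	0.442	0.976	-1.893	-0.746	-0.143	0.03	-0.897	-1.224	-0.147	-0.622	0.488	1.388
synthetic_scale_12	0.008	0.201	-1.227	-1.553	-2.065	0.047	-0.002	-0.453	0.721	-0.137	-0.56	-0.656	0.696	0.519	0.092	0.557	-0.58	-0.706	-0.306	-1.778
synthetic_scale_13	-1.19	-0.377	-0.243	0.542	-0.013	0.861	-1.718	1.167	1.453	0.304	-0.936	0.646	1.382	0.354	1.656	-0.63	0.094	-0.46	-1.597	-1.024
synthetic_scale_14	0.18	0.031	0.893	0.089	-0.156	1.418	0.249	0.458	0.493	-0.373	0.266	-0.522	1.301	-0.921	2.308	0.101	-0.599	-1.507	-0.357	0.689
synthetic_scale_15	0.487	0.495	-0.324	-0.324	0.08	-1.443	0.995	0.399	-1.423	0.88	1.076	-1.108	-1.582	-1.286	-0.771	-1.47	1.057	0.523	-0.575	0.648
synthetic_scale_16	-0.623	0.077	0.375	3.215	-0.717	-2.418	0.802	-1.008	0.819	0.127	-1.091	0.213	-0.914	0.984	-0.364	2.15	-1.885	-0.886	0.058	-0.036
synthetic_scale_17	0.021	0.74	1.746	0.328	-0.969	1.921	1.338	-0.826	0.34	0.347	2.516	-0.966	-0.61	0.292	-1.826	-1.178	-0.917	2.174	-0.044	-1.166
synthetic_scale_18	-0.633	0.915	-0.158	1.239	0.495	0.273	0.937	-1.086	0.78	-1.564	-1.777	0.152	1.374	1.411	-0.401	1.539	0.273	0.721	0.093	-1.057
synthetic_scale_19	0.097	0.53	0.672	-0.679	-0.115	-0.571	1.498	0.463	0.06	1.626	0.423	-0.844	-0.559	0.615	0.499	0.743	-1.092	-0.916	-0.107	0.679
synthetic_scale_20	0.521	-0.364	0.041	0.542	0.307	-0.233	-1.973	0.062	0.234	-1.071	-0.037	0.197	-1.068	-0.909	-0.998	-0.677	-0.058	-0.885	0.896	2.061
synthetic_scale_21	-0.052	-0.369	0.975	-0.355	0.559	2.298	-2.332	-1.278	0.598	0.899	0.787	0.63	0.199	1.945	0.676	0.697	-0.225	-1.108	0.167	1.097
synthetic_scale_22	0.788	0.557	-0.677	0.425	0.069	-0.4	-1.374	0.498	0.15	0.362	-1.422	0.136	0.701	-0.657	-0.401	1.238	-0.364	-1.633	0.317	-0.981
synthetic_scale_23	-0.092	0.101	2.218	-1.105	0.84	0.306	0.621	1.856	0.22	-1.327	-0.562	-1.022	0.51	0.052	0.302	-0.195	1.04	-0.395	2.25	0.101
synthetic_scale_24	0.477	1.742	0.377	-0.464	-1.23	-0.341	-0.025	0.054	-0.345	-0.447	0.024	0.523	-2.898	-0.338	0.114	0.431	-0.022	-0.227	-1.128	-0.78
synthetic_scale_25	1.322	-2.426	-0.589	-0.96	0.189	0.681	-0.564	-0.446	-0.321	0.056	-1.175	-0.03	-1.008	-1.721	0.629	0.824	0.92	0.29	-0.563	-0.125
synthetic_scale_26	1.703	1.118	-0.626	0.81	0.404	0.574	1.559	0.293	-0.686	-0.531	0.108	2.606	-2.552	-1.297	0.953	0.245	-2.234	0.233	0.89	-0.186
synthetic_scale_27	0.818	-0.905	-1.029	0.711	0.901	0.179	-0.203	-0.187	-0.836	-0.216	0.557	-0.03	-2.292	0.169	-1.202	-2.113	1.209	-0.59	0.705	1.425
synthetic_scale_28	0.391	2.265	-0.575	0.094	1.406	0.752	-1.185	-1.569	0.568	0.517	-0.083	1.345	1.092	1.287	1.66	0.654	0.02	-0.574	1.17	-0.367
synthetic_scale_29	-0.894	-0.802	-0.481	-0.466	1.457	-0.947	-1.258	0.305	-0.581	0.594	0.321	-0.294	1.277	2.078	-1.324	2.083	0.974	0.553	-1.773	2.177
synthetic_scale_30	0.832	1.961	-0.983	1.713	0.758	-0.679	1.289	0.934	0.029	-0.043	2.29	0.72	-1.243	0.513	-0.562	-0.173	-0.257	1.087	0.383	-0.56
synthetic_scale_31	0.036	-1.263	-0.061	0.256	0.675	-1.915	0.896	0.316	0.334	-0.313	-0.074	2.957	0.735	-0.182	0.1	-0.618	0.131	-0.625	-1.032	1.082
synthetic_scale_32	-0.827	-0.703	0.957	-0.739	-0.332	-0.919	0.592	-0.236	-1.781	1.376	1.26	-0.438	0.7	0.08	2.131	-1.082	0.061	-0.36	1.811	1.769
synthetic_scale_33	-1.008	-1.565	0.447	1.403	-0.885	0.246	0.795	0.537	0.609	-0.447	-1.234	-0.066	-0.39	0.457	0.12	0.808	0.387	0.312	1.084	-0.513
synthetic_scale_34	-0.708	-1.226	0.432	-0.369	1.48	0.262	-1.619	-0.7	0.358	1.819	0.165	0.885	1.433	1.42	1.508	-2.611	-0.532	-1.824	-0.3	0.224
synthetic_scale_35	-1.089	0.793	-1.017	0.506	1.444	0.04	1.297	1.42	-0.362	0.998	-0.803	-0.114	0.026	-0.334	-0.519	-0.713	-0.171	-0.446	1.195	0.406
synthetic_scale_36	-1.621	0.696	-1.921	-0.047	0.249	0.218	2.731	-0.202	-0.331	-0.492	1.867	-0.915	-0.217	-1.405	0.95	-0.382	0.384	-0.632	-1.078	-0.413
synthetic_scale_37	1.569	1.202	1.592	0.201	-0.28	1.76	0.305	-0.118	0.98	0.102	1.03	-0.543	-0.619	-2.032	0.318	1.221	-0.665	0.216	0.286	1.703
synthetic_scale_38	-0.669	-0.921	0.597	1.481	1.037	0.326	-0.638	-1.176	-0.484	0.461	1.295	0.407	-1.871	0.073	0.146	0.963	0.337	-0.868	-0.475	-0.483
synthetic_scale_39	-0.03	0.624	-0.055	0.473	-0.279	0.884	1.961	-0.298	1.567	-0.516	-1.472	1.233	-0.692	-0.933	-0.065	-0.756	-0.247	0.738	1.316	0.026
synthetic_scale_40	-1.228	-0.935	0.092	0.903	0.565	-1.465	-1.69	-0.471	-0.433	-1.095	-0.896	-0.927	-0.472	0.746	-0.805	0.611	-0.871	0.826	0.383	1.053
synthetic_scale_41	-0.387	-0.859	1.133	-0.01	-0.778	0.012	-0.19	-1.322	0.523	0.306	-1.978	-0.473	1.091	0.236	-0.14	0.113	-0.08	0.63	-1.292	-0.687
synthetic_scale_42	0.341	0.03	0.161	1.217	-0.803	-1.501	0.945	2.253	0.496	-1.968	0.682	-1.783	-1.101	-0.998	1.232	-0.852	2.263	-1.066	1.007	-1.851
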