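# Synthetic pairwise contact free energies U(a,b) in kT units.
# Constructed from normalized Kyte-Doolittle hydropathies: burial of
# hydrophobic pairs is favourable, polarity mismatch is penalized, plus a
# symmetric seeded perturbation providing pair-specific preferences. Stands in for a
# statistically derived contact potential; override via configuration.
#	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	-0.667301	0.658964	0.381354	0.140045	-0.841386	0.340678	0.585639	-0.562515	-0.003804	-0.209280	-0.629551	0.198404	-0.506545	-0.778410	-0.461933	-0.188011	-0.330103	-0.385124	-0.605996	-0.888870
R	0.658964	-0.002641	-0.031733	0.047894	0.780482	-0.032001	-0.355617	0.427202	0.146194	1.650077	1.159720	-0.121327	0.764578	1.059884	-0.178976	0.100460	0.003050	-0.096592	0.015192	1.357402
N	0.381354	-0.031733	0.066171	0.059557	0.590774	-0.157564	-0.173212	0.294578	-0.079583	0.998502	0.820679	-0.053476	0.322932	0.513072	-0.184061	-0.114003	-0.018667	-0.257259	-0.063707	0.959351
D	0.140045	0.047894	0.059557	-0.142255	0.440390	-0.208114	-0.042984	-0.156010	-0.092501	1.046211	0.852352	-0.203928	0.272888	0.490970	-0.310553	-0.176606	-0.027329	-0.334419	0.174828	1.142144
C	-0.841386	0.780482	0.590774	0.440390	-0.620524	0.410080	0.130452	-0.633844	0.518001	-0.626419	-0.749120	0.577678	-0.774019	-0.836876	-0.139970	-0.385331	-0.087527	-0.442802	-0.348359	-0.739838
Q	0.340678	-0.032001	-0.157564	-0.208114	0.410080	-0.279737	-0.178410	0.068480	-0.236908	1.172031	0.893088	-0.260232	0.215952	0.487651	-0.211380	-0.147026	-0.103220	-0.315309	0.008877	1.189318
E	0.585639	-0.355617	-0.173212	-0.042984	0.130452	-0.178410	-0.055494	0.008107	-0.014764	1.126276	0.905778	-0.110414	0.143992	0.549983	-0.062945	-0.124778	-0.167967	-0.099188	-0.057253	0.960526
G	-0.562515	0.427202	0.294578	-0.156010	-0.633844	0.068480	0.008107	-0.525377	-0.313245	-0.096234	-0.152155	0.052748	-0.455437	-0.384091	-0.284033	-0.531197	-0.673341	-0.609399	-0.216283	-0.273301
H	-0.003804	0.146194	-0.079583	-0.092501	0.518001	-0.236908	-0.014764	-0.313245	-0.110455	0.843375	0.635929	-0.106656	0.055327	0.615143	-0.458831	-0.267570	-0.400491	-0.337135	0.034399	0.864232
I	-0.209280	1.650077	0.998502	1.046211	-0.626419	1.172031	1.126276	-0.096234	0.843375	-1.091542	-1.138418	1.085045	-0.637863	-0.921946	0.373645	0.033545	-0.148815	0.015902	0.076821	-0.897388
L	-0.629551	1.159720	0.820679	0.852352	-0.749120	0.893088	0.905778	-0.152155	0.635929	-1.138418	-0.872942	0.671844	-0.845529	-0.848764	-0.012196	-0.156198	-0.125835	-0.176558	0.071474	-0.920149
K	0.198404	-0.121327	-0.053476	-0.203928	0.577678	-0.260232	-0.110414	0.052748	-0.106656	1.085045	0.671844	0.040484	0.511505	0.756088	0.110021	-0.016907	-0.016896	0.055630	-0.156828	1.298900
M	-0.506545	0.764578	0.322932	0.272888	-0.774019	0.215952	0.143992	-0.455437	0.055327	-0.637863	-0.845529	0.511505	-0.901103	-1.000967	-0.178776	-0.283664	-0.498257	-0.218564	-0.330772	-0.766291
F	-0.778410	1.059884	0.513072	0.490970	-0.836876	0.487651	0.549983	-0.384091	0.615143	-0.921946	-0.848764	0.756088	-1.000967	-0.737982	-0.165023	-0.098402	-0.382103	-0.119831	-0.307408	-1.021934
P	-0.461933	-0.178976	-0.184061	-0.310553	-0.139970	-0.211380	-0.062945	-0.284033	-0.458831	0.373645	-0.012196	0.110021	-0.178776	-0.165023	-0.352111	-0.360355	-0.331692	-0.241396	0.023788	0.091657
S	-0.188011	0.100460	-0.114003	-0.176606	-0.385331	-0.147026	-0.124778	-0.531197	-0.267570	0.033545	-0.156198	-0.016907	-0.283664	-0.098402	-0.360355	-0.231260	-0.390044	-0.387557	-0.422732	-0.146850
T	-0.330103	0.003050	-0.018667	-0.027329	-0.087527	-0.103220	-0.167967	-0.673341	-0.400491	-0.148815	-0.125835	-0.016896	-0.498257	-0.382103	-0.331692	-0.390044	-0.442924	-0.164411	-0.427692	-0.273521
W	-0.385124	-0.096592	-0.257259	-0.334419	-0.442802	-0.315309	-0.099188	-0.609399	-0.337135	0.015902	-0.176558	0.055630	-0.218564	-0.119831	-0.241396	-0.387557	-0.164411	-0.099251	-0.366044	-0.032879
Y	-0.605996	0.015192	-0.063707	0.174828	-0.348359	0.008877	-0.057253	-0.216283	0.034399	0.076821	0.071474	-0.156828	-0.330772	-0.307408	0.023788	-0.422732	-0.427692	-0.366044	-0.596546	-0.038810
V	-0.888870	1.357402	0.959351	1.142144	-0.739838	1.189318	0.960526	-0.273301	0.864232	-0.897388	-0.920149	1.298900	-0.766291	-1.021934	0.091657	-0.146850	-0.273521	-0.032879	-0.038810	-0.966365
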