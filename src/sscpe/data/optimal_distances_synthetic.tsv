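# Synthetic optimal closest-heavy-atom contact distances d(a,b) in Angstrom,
# modeled as the sum of effective residue radii r(a) = 1.1 + 0.35 * s(a)^(1/3)
# where s(a) is the heavy-atom count. Stands in for distances measured on a
# nonredundant structure set; override via configuration.
#	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	3.396983	3.576885	3.498492	3.498492	3.434484	3.526521	3.526521	3.354082	3.552544	3.498492	3.498492	3.526521	3.498492	3.576885	3.468017	3.434484	3.468017	3.642041	3.599792	3.468017
R	3.576885	3.756786	3.678393	3.678393	3.614385	3.706422	3.706422	3.533983	3.732445	3.678393	3.678393	3.706422	3.678393	3.756786	3.647919	3.614385	3.647919	3.821943	3.779693	3.647919
N	3.498492	3.678393	3.600000	3.600000	3.535992	3.628029	3.628029	3.455590	3.654052	3.600000	3.600000	3.628029	3.600000	3.678393	3.569526	3.535992	3.569526	3.743550	3.701300	3.569526
D	3.498492	3.678393	3.600000	3.600000	3.535992	3.628029	3.628029	3.455590	3.654052	3.600000	3.600000	3.628029	3.600000	3.678393	3.569526	3.535992	3.569526	3.743550	3.701300	3.569526
C	3.434484	3.614385	3.535992	3.535992	3.471984	3.564022	3.564022	3.391583	3.590044	3.535992	3.535992	3.564022	3.535992	3.614385	3.505518	3.471984	3.505518	3.679542	3.637292	3.505518
Q	3.526521	3.706422	3.628029	3.628029	3.564022	3.656059	3.656059	3.483620	3.682081	3.628029	3.628029	3.656059	3.628029	3.706422	3.597555	3.564022	3.597555	3.771579	3.729329	3.597555
E	3.526521	3.706422	3.628029	3.628029	3.564022	3.656059	3.656059	3.483620	3.682081	3.628029	3.628029	3.656059	3.628029	3.706422	3.597555	3.564022	3.597555	3.771579	3.729329	3.597555
G	3.354082	3.533983	3.455590	3.455590	3.391583	3.483620	3.483620	3.311181	3.509643	3.455590	3.455590	3.483620	3.455590	3.533983	3.425116	3.391583	3.425116	3.599140	3.556890	3.425116
H	3.552544	3.732445	3.654052	3.654052	3.590044	3.682081	3.682081	3.509643	3.708104	3.654052	3.654052	3.682081	3.654052	3.732445	3.623578	3.590044	3.623578	3.797602	3.755352	3.623578
I	3.498492	3.678393	3.600000	3.600000	3.535992	3.628029	3.628029	3.455590	3.654052	3.600000	3.600000	3.628029	3.600000	3.678393	3.569526	3.535992	3.569526	3.743550	3.701300	3.569526
L	3.498492	3.678393	3.600000	3.600000	3.535992	3.628029	3.628029	3.455590	3.654052	3.600000	3.600000	3.628029	3.600000	3.678393	3.569526	3.535992	3.569526	3.743550	3.701300	3.569526
K	3.526521	3.706422	3.628029	3.628029	3.564022	3.656059	3.656059	3.483620	3.682081	3.628029	3.628029	3.656059	3.628029	3.706422	3.597555	3.564022	3.597555	3.771579	3.729329	3.597555
M	3.498492	3.678393	3.600000	3.600000	3.535992	3.628029	3.628029	3.455590	3.654052	3.600000	3.600000	3.628029	3.600000	3.678393	3.569526	3.535992	3.569526	3.743550	3.701300	3.569526
F	3.576885	3.756786	3.678393	3.678393	3.614385	3.706422	3.706422	3.533983	3.732445	3.678393	3.678393	3.706422	3.678393	3.756786	3.647919	3.614385	3.647919	3.821943	3.779693	3.647919
P	3.468017	3.647919	3.569526	3.569526	3.505518	3.597555	3.597555	3.425116	3.623578	3.569526	3.569526	3.597555	3.569526	3.647919	3.539052	3.505518	3.539052	3.713076	3.670826	3.539052
S	3.434484	3.614385	3.535992	3.535992	3.471984	3.564022	3.564022	3.391583	3.590044	3.535992	3.535992	3.564022	3.535992	3.614385	3.505518	3.471984	3.505518	3.679542	3.637292	3.505518
T	3.468017	3.647919	3.569526	3.569526	3.505518	3.597555	3.597555	3.425116	3.623578	3.569526	3.569526	3.597555	3.569526	3.647919	3.539052	3.505518	3.539052	3.713076	3.670826	3.539052
W	3.642041	3.821943	3.743550	3.743550	3.679542	3.771579	3.771579	3.599140	3.797602	3.743550	3.743550	3.771579	3.743550	3.821943	3.713076	3.679542	3.713076	3.887100	3.844850	3.713076
Y	3.599792	3.779693	3.701300	3.701300	3.637292	3.729329	3.729329	3.556890	3.755352	3.701300	3.701300	3.729329	3.701300	3.779693	3.670826	3.637292	3.670826	3.844850	3.802600	3.670826
V	3.468017	3.647919	3.569526	3.569526	3.505518	3.597555	3.597555	3.425116	3.623578	3.569526	3.569526	3.597555	3.569526	3.647919	3.539052	3.505518	3.539052	3.713076	3.670826	3.539052
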