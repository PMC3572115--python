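pathway	ks	absm	ganpa	goganpa_iea	goganpa
p53 hypoxia pathway	0.001	0.015	0.01	0.005	0.015
hsp27 pathway	0.002	0.033	0.09	0.029	0.033
p53 pathway	0.006	0.015	0	0	0.01
p53 up	0.01	0.015	0	0	0
radiation sensitivity	0.064	0.015	0	0	0.014
ck1 pathway	0.474	0.178	0.157	0.139	0.145
bad pathway	0.507	0.079	0.125	0.049	0.067
p53 signalling	0.517	0.22	0.125	0.041	0.209
st dictyostelium	0.788	0.178	0.157	0.106	0.145
G2 pathway	0.8	0.22	0.198	0.106	0.212
bcl2 family and reg network	0.828	0.22	0.125	0.08	0.141
DNA damage signalling	0.862	0.178	0.198	0.2	0.141
ceramide pathway	0.874	0.189	0.157	0.038	0.177
mitochondria pathway	0.881	0.178	0.127	0.106	0.044
cell cycle pathway	0.899	0.178	0.151	0.107	0.145
cell cycle arrest	0.958	0.22	0.157	0.095	0.209
cell cycle regulator	0.969	0.178	0.125	0.078	0.152
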