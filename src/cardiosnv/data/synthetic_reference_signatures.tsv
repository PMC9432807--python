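context	SBS5_like	SBS18_like	SBS44_like	scE_like	scF_like
A[C>A]A	0.00570383	0.0819027	0.00232359	0.000977657	0.000550493
A[C>A]C	0.00358087	0.0254101	0.00140049	0.000850584	0.00053159
A[C>A]G	0.00515623	0.0186727	0.00127949	0.000686065	0.000470386
A[C>A]T	0.00388318	0.0725635	0.00145089	0.000964439	0.000372815
C[C>A]A	0.00420129	0.10061	0.0375902	0.000842039	0.000678497
C[C>A]C	0.00521471	0.0363051	0.0311748	0.0010465	0.000453034
C[C>A]G	0.0059497	0.06808	0.023933	0.000938964	0.000504224
C[C>A]T	0.00688004	0.0866611	0.0437848	0.00096443	0.000548647
G[C>A]A	0.00398061	0.0758119	0.0018985	0.000788644	0.000422001
G[C>A]C	0.00595576	0.0316276	0.00160295	0.000610942	0.000342973
G[C>A]G	0.00484406	0.027117	0.00179884	0.000838614	0.000448798
G[C>A]T	0.00366974	0.0433667	0.00229383	0.000924037	0.000453874
T[C>A]A	0.00530159	0.079759	0.0021088	0.00047414	0.0211937
T[C>A]C	0.00424389	0.0276993	0.00124359	0.00129384	0.0155092
T[C>A]G	0.00534717	0.0392208	0.00188526	0.0011951	0.0157296
T[C>A]T	0.00437864	0.0789204	0.00151139	0.000523194	0.0285579
A[C>G]A	0.00468602	0.00156194	0.0017668	0.000885885	0.000487892
A[C>G]C	0.00318771	0.0011909	0.00159031	0.00111238	0.000514294
A[C>G]G	0.00384716	0.00184207	0.0021804	0.00108436	0.000534659
A[C>G]T	0.0034698	0.00168574	0.0018128	0.000967813	0.000470122
C[C>G]A	0.0041322	0.00133567	0.00189738	0.00130521	0.000795425
C[C>G]C	0.00310443	0.00152581	0.00158945	0.000835247	0.000433874
C[C>G]G	0.00368541	0.00120192	0.00252107	0.000472823	0.000374154
C[C>G]T	0.00451226	0.00148714	0.00220695	0.000799379	0.000464532
G[C>G]A	0.00567423	0.00160206	0.0014228	0.00105199	0.000621505
G[C>G]C	0.00451479	0.00149226	0.00149139	0.000977004	0.000444406
G[C>G]G	0.0056131	0.0013551	0.00229946	0.00090716	0.00061661
G[C>G]T	0.00403242	0.00124938	0.00218146	0.000960004	0.00059661
T[C>G]A	0.00431426	0.00245229	0.00174374	0.0005295	0.000858495
T[C>G]C	0.00627714	0.00135759	0.0014771	0.00108554	0.000435805
T[C>G]G	0.00539529	0.0018144	0.00196929	0.000951678	0.000506343
T[C>G]T	0.00313902	0.00118534	0.00207494	0.000971734	0.000640457
A[C>T]A	0.0245218	0.00135342	0.00147678	0.060847	0.000576278
A[C>T]C	0.0254553	0.00126533	0.00158402	0.0881878	0.000364127
A[C>T]G	0.014215	0.000660826	0.139639	0.000836052	0.000414785
A[C>T]T	0.0210276	0.00157855	0.00178803	0.051653	0.000717751
C[C>T]A	0.0265527	0.00196781	0.00135524	0.00131068	0.121229
C[C>T]C	0.0207233	0.000947378	0.0016583	0.00101626	0.145971
C[C>T]G	0.0184279	0.00124479	0.120372	0.000676708	0.000526421
C[C>T]T	0.0131237	0.00169496	0.00125538	0.000761481	0.165965
G[C>T]A	0.0230768	0.00148538	0.00225508	0.129946	0.000475642
G[C>T]C	0.0120829	0.00155287	0.00244639	0.10021	0.000651585
G[C>T]G	0.0264681	0.00126075	0.126414	0.000613703	0.000760971
G[C>T]T	0.022321	0.00150576	0.00122368	0.0913106	0.000521185
T[C>T]A	0.0092917	0.00106383	0.00152558	0.000767017	0.145922
T[C>T]C	0.01547	0.00147272	0.00123747	0.00108082	0.187414
T[C>T]G	0.025778	0.00129153	0.10534	0.000586365	0.000446618
T[C>T]T	0.0220986	0.000713622	0.00240075	0.000945636	0.104771
A[T>A]A	0.00401511	0.00141555	0.00216464	0.000975638	0.000574387
A[T>A]C	0.00505165	0.00118592	0.00211813	0.00101692	0.000377513
A[T>A]G	0.00687405	0.0010544	0.00230724	0.000754104	0.000609241
A[T>A]T	0.00362581	0.00105236	0.00169149	0.00100302	0.000572632
C[T>A]A	0.00406321	0.000998274	0.00216979	0.000949654	0.00051347
C[T>A]C	0.00638703	0.00122252	0.0013944	0.000704927	0.000642875
C[T>A]G	0.00537892	0.00111729	0.00167564	0.000625105	0.000633585
C[T>A]T	0.00424162	0.00143391	0.00181328	0.000764801	0.000722763
G[T>A]A	0.00596201	0.00186531	0.00189431	0.000937257	0.000450919
G[T>A]C	0.0060043	0.00114616	0.0020541	0.00101811	0.00081223
G[T>A]G	0.00669149	0.00154153	0.00238681	0.000711165	0.000496182
G[T>A]T	0.00763607	0.00101882	0.0016146	0.00087596	0.000451944
T[T>A]A	0.00374606	0.00146494	0.00239196	0.000996199	0.00050104
T[T>A]C	0.00411942	0.00148567	0.00141528	0.00069708	0.000560987
T[T>A]G	0.00697736	0.00126569	0.00267396	0.000915451	0.000475541
T[T>A]T	0.0055855	0.000956081	0.00129266	0.000654757	0.00078884
A[T>C]A	0.0221238	0.00166363	0.0656878	0.000762141	0.000518959
A[T>C]C	0.0233956	0.0016881	0.0458039	0.000770276	0.000523629
A[T>C]G	0.0226269	0.00190406	0.0532674	0.000865023	0.000797734
A[T>C]T	0.020283	0.00172364	0.0553612	0.000568927	0.000736603
C[T>C]A	0.0205692	0.000894003	0.0015689	0.000611089	0.000664327
C[T>C]C	0.0288583	0.00116799	0.00145527	0.00123388	0.000579433
C[T>C]G	0.0253085	0.00106244	0.00194698	0.00101943	0.000607666
C[T>C]T	0.0314767	0.00127358	0.00115326	0.000652233	0.000619113
G[T>C]A	0.0219085	0.00148107	0.00153719	0.000864992	0.000762719
G[T>C]C	0.0220055	0.00128235	0.00186852	0.000617134	0.000647099
G[T>C]G	0.027261	0.00135443	0.00176317	0.000592416	0.000417943
G[T>C]T	0.0291672	0.00137792	0.00160141	0.000865248	0.000441387
T[T>C]A	0.0191511	0.00120088	0.00121076	0.000602611	0.000500683
T[T>C]C	0.0295046	0.0010579	0.00262315	0.000762303	0.000562216
T[T>C]G	0.020197	0.00161413	0.00252347	0.00107443	0.000541007
T[T>C]T	0.0122073	0.00124629	0.00103614	0.000647762	0.000477048
A[T>G]A	0.00236083	0.00111245	0.00146046	0.0228199	0.000456195
A[T>G]C	0.00538603	0.00113859	0.00163017	0.0320833	0.000536215
A[T>G]G	0.00455877	0.00156952	0.00153149	0.0227481	0.000475943
A[T>G]T	0.00323813	0.000818114	0.00214999	0.0223934	0.00078357
C[T>G]A	0.00527033	0.00133197	0.00214216	0.0290731	0.00044853
C[T>G]C	0.00415127	0.00116521	0.00196584	0.0195119	0.000678654
C[T>G]G	0.00449151	0.000606837	0.001183	0.0433886	0.000887956
C[T>G]T	0.00320711	0.00126902	0.00191175	0.0329787	0.000660513
G[T>G]A	0.00348028	0.00126463	0.00171789	0.018519	0.000636424
G[T>G]C	0.00376579	0.00103153	0.00159251	0.0190919	0.00041771
G[T>G]G	0.00366203	0.00123043	0.00200307	0.0232828	0.000483397
G[T>G]T	0.00411225	0.00108565	0.0025337	0.0285382	0.000437779
T[T>G]A	0.00289806	0.00130856	0.00176922	0.0200191	0.000290599
T[T>G]C	0.00592143	0.00155445	0.00174918	0.0286151	0.000593154
T[T>G]G	0.00680534	0.00102028	0.00219231	0.025795	0.000578739
T[T>G]T	0.00577612	0.00114942	0.0015215	0.0254661	0.000763228
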