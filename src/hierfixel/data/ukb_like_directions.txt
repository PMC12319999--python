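# Two-shell diffusion-encoding direction set (synthetic, electrostatic repulsion)
# columns: b[ms/um^2] gx gy gz ; 25 directions per shell
1.0  0.9265632901 -0.2633459285 -0.2685691558
1.0  0.1839339920  0.4564371644  0.8705362724
1.0  0.6030282916 -0.3854558537  0.6984129612
1.0  0.0487573938  0.2214023314 -0.9739628967
1.0  0.3944952272  0.0084862490  0.9188588027
1.0  0.6748696797 -0.0594126077 -0.7355413363
1.0  0.5598377259 -0.7497293301  0.3528280774
1.0  0.2564434726  0.7831662377 -0.5664692308
1.0  0.7555802219  0.6294351821  0.1814108039
1.0  0.1747367715 -0.7361404627 -0.6538839957
1.0  0.8850821308  0.2464731151 -0.3948172049
1.0  0.9806185646  0.1746959381  0.0887049042
1.0  0.6743761785  0.6707488384 -0.3087276561
1.0  0.3040870572  0.8340815697  0.4602597058
1.0  0.1703624504 -0.6218820863  0.7643554842
1.0  0.6074224218 -0.5359907884 -0.5863035700
1.0  0.3283391270  0.9442662062 -0.0235531233
1.0  0.6535886775 -0.7444597304 -0.1363875014
1.0  0.4796988027  0.3955500600 -0.7832172168
1.0  0.9021027551 -0.3739339820  0.2153694417
1.0  0.8383510554  0.0325838943  0.5441560417
1.0  0.1270669267 -0.9498282632  0.2857975972
1.0  0.2558942955 -0.2348558780 -0.9377424092
1.0  0.1903015926 -0.9593170428 -0.2085572227
1.0  0.6271868128  0.4565621716  0.6310211448
2.0  0.3276640525 -0.4845539186 -0.8110756862
2.0  0.4915455583 -0.7218908528  0.4870898899
2.0  0.4288607205 -0.2925640519  0.8546840106
2.0  0.6995608571  0.5391257832  0.4689967986
2.0  0.0841360806  0.9907809867  0.1061798305
2.0  0.6564569911 -0.6600662828 -0.3652077781
2.0  0.4758690761 -0.0148274313 -0.8793911358
2.0  0.0051105534  0.0947433587 -0.9954886128
2.0  0.9389225496  0.1207272611  0.3222566902
2.0  0.0298931678  0.9227325678 -0.3842798549
2.0  0.2056331725 -0.8459342297 -0.4920470277
2.0  0.0613571157 -0.6282323872  0.7756025864
2.0  0.8053779063  0.2826375291 -0.5210397828
2.0  0.9879679689 -0.0860681815 -0.1284973172
2.0  0.3945275970  0.4737214993 -0.7873600932
2.0  0.5928899883  0.1719095237  0.7867201392
2.0  0.5183083335  0.7575449524 -0.3968401650
2.0  0.1517885370  0.3756076070  0.9142642756
2.0  0.8805310339  0.4692529120 -0.0668341447
2.0  0.8414015751 -0.5344595872  0.0799771159
2.0  0.5401022000  0.8362506426  0.0947337121
2.0  0.4167328770 -0.9084482131  0.0324892793
2.0  0.2699632242  0.7512366980  0.6022983323
2.0  0.7926116109 -0.2412959793 -0.5599491804
2.0  0.8025730781 -0.2981665500  0.5166944578
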