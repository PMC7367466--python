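,bio1,bio2,bio3,bio4,bio5,bio6,bio7,bio8,bio9,bio10,bio11,bio12,bio13,bio14,bio15,bio16,bio17,bio18,bio19
bio1,1.0,-0.012423,0.281879,-0.27752,0.958739,0.95901,0.009354,0.944696,0.944541,0.981253,0.980884,-0.011267,0.001372,-0.011359,0.005217,-0.00332,-0.004619,-0.012447,-0.004451
bio2,-0.012423,1.0,0.927506,-0.001961,-0.012115,-0.007431,-8.7e-05,-0.00959,-0.009514,-0.010497,-0.013387,0.00866,0.019935,0.01115,0.026365,0.023325,0.014871,0.010221,0.012109
bio3,0.281879,0.927506,1.0,-0.079284,0.269382,0.275919,0.007579,0.269463,0.26761,0.27852,0.274987,0.004799,0.015735,0.006498,0.022952,0.016694,0.014004,0.006814,0.008283
bio4,-0.27752,-0.001961,-0.079284,1.0,-0.264419,-0.270631,0.930288,-0.263724,-0.26023,-0.273702,-0.269801,-0.024054,-0.006502,-0.018136,-0.011619,0.001374,-0.019188,-0.020627,-0.016007
bio5,0.958739,-0.012115,0.269382,-0.264419,1.0,0.921894,0.011922,0.906694,0.907918,0.940335,0.940226,-0.013233,0.001716,-0.013358,0.004715,-0.003588,-0.008551,-0.013203,-0.006637
bio6,0.95901,-0.007431,0.275919,-0.270631,0.921894,1.0,0.005063,0.903587,0.906082,0.940151,0.940916,-0.011974,0.000965,-0.010726,0.002899,-0.004667,-0.005996,-0.009293,-0.004732
bio7,0.009354,-8.7e-05,0.007579,0.930288,0.011922,0.005063,1.0,0.00963,0.009799,0.006284,0.012346,-0.028917,-0.010452,-0.022951,-0.013231,-0.003899,-0.022319,-0.026532,-0.019089
bio8,0.944696,-0.00959,0.269463,-0.263724,0.906694,0.903587,0.00963,1.0,0.892178,0.927255,0.925614,-0.015563,-0.005477,-0.016579,-9.6e-05,-0.010358,-0.01022,-0.017038,-0.009811
bio9,0.944541,-0.009514,0.26761,-0.26023,0.907918,0.906082,0.009799,0.892178,1.0,0.927484,0.927052,-0.001585,0.008267,-0.001431,0.010064,0.003218,0.004284,-0.002506,0.004345
bio10,0.981253,-0.010497,0.27852,-0.273702,0.940335,0.940151,0.006284,0.927255,0.927484,1.0,0.962865,-0.006506,0.007064,-0.006543,0.011482,0.000523,-0.001478,-0.008733,-0.000855
bio11,0.980884,-0.013387,0.274987,-0.269801,0.940226,0.940916,0.012346,0.925614,0.927052,0.962865,1.0,-0.009208,0.001377,-0.009464,0.006493,-0.003269,-0.002943,-0.011385,-0.001873
bio12,-0.011267,0.00866,0.004799,-0.024054,-0.013233,-0.011974,-0.028917,-0.015563,-0.001585,-0.006506,-0.009208,1.0,0.36409,0.957839,0.3409,0.35206,0.969876,0.957641,0.945189
bio13,0.001372,0.019935,0.015735,-0.006502,0.001716,0.000965,-0.010452,-0.005477,0.008267,0.007064,0.001377,0.36409,1.0,0.350654,0.952234,0.964876,0.355607,0.354548,0.340766
bio14,-0.011359,0.01115,0.006498,-0.018136,-0.013358,-0.010726,-0.022951,-0.016579,-0.001431,-0.006543,-0.009464,0.957839,0.350654,1.0,0.329312,0.338191,0.927552,0.91754,0.904641
bio15,0.005217,0.026365,0.022952,-0.011619,0.004715,0.002899,-0.013231,-9.6e-05,0.010064,0.011482,0.006493,0.3409,0.952234,0.329312,1.0,0.919596,0.331931,0.333456,0.320634
bio16,-0.00332,0.023325,0.016694,0.001374,-0.003588,-0.004667,-0.003899,-0.010358,0.003218,0.000523,-0.003269,0.35206,0.964876,0.338191,0.919596,1.0,0.345087,0.344128,0.330374
bio17,-0.004619,0.014871,0.014004,-0.019188,-0.008551,-0.005996,-0.022319,-0.01022,0.004284,-0.001478,-0.002943,0.969876,0.355607,0.927552,0.331931,0.345087,1.0,0.92988,0.91738
bio18,-0.012447,0.010221,0.006814,-0.020627,-0.013203,-0.009293,-0.026532,-0.017038,-0.002506,-0.008733,-0.011385,0.957641,0.354548,0.91754,0.333456,0.344128,0.92988,1.0,0.90157
bio19,-0.004451,0.012109,0.008283,-0.016007,-0.006637,-0.004732,-0.019089,-0.009811,0.004345,-0.000855,-0.001873,0.945189,0.340766,0.904641,0.320634,0.330374,0.91738,0.90157,1.0
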