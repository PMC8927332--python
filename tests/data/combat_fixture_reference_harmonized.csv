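,feat_0,feat_1,feat_2,feat_3,feat_4
S00,-1.2812588910114693e+00,-1.0294481645174047e+00,-8.0232738675166471e-01,1.5164885118897728e+00,4.7979505503709918e-01
S01,9.9544121614697367e-01,5.2032260628075866e-01,2.4935028673607484e-01,-1.1936854128271790e-01,1.8974400783760839e+00
S02,-5.3434736727213439e-01,-2.2085410343167973e+00,-4.8183644095655576e-01,1.3903296994780230e+00,3.8770719263266790e-01
S03,2.1429506476553253e+00,2.0032442284000034e+00,-7.8584353684307717e-01,1.6415489271507600e+00,-9.2561173209728764e-01
S04,9.8433493452659437e-01,-9.6727538226661269e-01,1.1691060878213946e+00,8.4009907236040071e-01,-2.2644408310474895e-01
S05,3.7258936083144700e-01,1.9986389958054551e+00,6.2533888969187690e-01,2.3564359211392403e+00,3.3519840624870301e-01
S06,6.2543975406263164e-01,-1.2823948043976452e+00,6.9524312190380799e-01,5.8918509842521627e-01,1.6597505875035123e+00
S07,1.1315011888986037e+00,2.0993330795093321e+00,-1.5043182825441277e+00,-1.0368132985305265e+00,1.1220809187263718e+00
S08,3.5642001666569390e-01,-3.8487790947206857e-01,-3.3983068293992502e-01,-1.0981113402168674e-01,4.1961489380896155e-01
S09,2.4130269539338687e+00,1.1449322869063743e+00,-4.7509716581162648e-01,1.9866497592896721e+00,-4.1780257595345183e-01
S10,-4.0450370485809628e-02,-1.1616869196234640e+00,-5.9408912945667813e-01,-7.7875634322206677e-02,1.3014343011933076e+00
S11,3.9184090186031395e-01,1.2900313406635551e+00,-5.2876121082560212e-01,3.5570716100178039e+00,-4.9091522893525297e-01
S12,1.4075215962043703e+00,-1.1285079578349484e+00,9.6994934301144309e-01,8.4382915995063867e-01,1.8104721067260093e-01
S13,1.7915590227204503e+00,2.2257350071126425e-01,-1.4623958701226675e-01,9.8496945954512072e-01,9.4494298814366318e-01
S14,7.0416680891798988e-01,-4.2756100115051310e-01,8.1233703524401968e-01,1.3009091024180379e+00,-1.1151778124123752e+00
S15,1.3094514547826441e+00,7.4623775439830997e-01,-1.4024088732937889e-01,1.4726715137648059e+00,2.1019369030962416e+00
S16,-1.7165908457940177e-01,-1.3077451174050352e+00,-1.2153584747094310e+00,1.4734656688962433e+00,1.1950648397964228e+00
S17,1.9264982246626876e+00,6.3176671043233734e-01,-1.3594649554403944e+00,9.2114094225048904e-02,1.4159820301836312e+00
S18,5.2249250318978580e-01,-3.0059804520569178e-01,-2.0406262936909840e+00,-9.0261667021170455e-01,-2.2002744410098274e-01
S19,5.3264511745219334e-01,1.6581500207835196e+00,-5.2828702653419946e-01,1.6209109603543219e+00,1.1055448579786287e+00
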