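sample_id,feat_0,feat_1,feat_2,feat_3,feat_4
S00,-1.8255070643,-0.9073985314,-0.5214195384,0.6400557865,0.2726093389
S01,0.4452160035,0.6491577354,0.474581933,-0.9350370121,1.6624823708
S02,-1.0820995266,-2.0748093715,-0.2146726651,0.5173836781,0.182917951
S03,1.587342124,2.1173871014,-0.5162181904,0.7772132417,-1.0871029533
S04,0.4294581809,-0.8458417348,1.3654701294,-0.0176399944,-0.4152507855
S05,-0.1747138669,2.1128274958,0.8344464779,1.472342604,0.1408961362
S06,0.0722466854,-1.1578390666,0.9119285081,-0.2616193536,1.4218579652
S07,0.5806376781,2.2125239386,-1.203881554,-1.8271259638,0.9073009893
S08,-0.1955109997,-0.2692144475,-0.0787567435,-0.941297134,0.2139952931
S09,1.8561514213,1.2675790071,-0.2187980013,1.1127763774,-0.5925089122
S10,-0.5905195488,-1.0383271123,-0.3221114607,-0.9102442491,1.072866424
S11,0.9623875846,1.1519881434,-0.8350388037,4.8919249167,-0.3980622647
S12,2.2076438775,-1.2882043527,0.8451607159,1.8929946209,0.405887647
S13,2.521318522,-0.0411613093,-0.3970717228,1.9781225988,1.2231536557
S14,1.4242850558,-0.5047219083,0.6647029377,2.4107969934,-1.0576695614
S15,1.9843729816,0.5441636509,-0.3902035281,2.5306151877,2.529506144
S16,0.4488371704,-1.4885464279,-1.6569014584,2.606277458,1.5508067653
S17,2.6716065646,0.4162138075,-1.7861507709,0.966652649,1.7550000351
S18,1.2219459623,-0.3628092484,-2.6017895775,-0.0854640912,-0.0469625076
S19,1.1192077647,1.5634522643,-0.8344958877,2.6985480371,1.4044879303
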