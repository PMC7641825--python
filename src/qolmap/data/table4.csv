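source,equation,term,value
eortc,logistic,intercept,-11.64060
eortc,logistic,pf,0.03395
eortc,logistic,rf,0.03742
eortc,logistic,ef,0.02694
eortc,logistic,ghs,0.03182
eortc,logistic,pa,-0.06337
eortc,beta,intercept,-1.66963
eortc,beta,female,0.15271
eortc,beta,pf,0.02475
eortc,beta,rf,0.00656
eortc,beta,ef,0.00540
eortc,beta,ghs,0.01167
eortc,beta,scale,8.09789
eortc,mo,intercept1,-5.91277
eortc,mo,intercept2,-3.79148
eortc,mo,intercept3,-1.85222
eortc,mo,intercept4,0.92106
eortc,mo,age,-0.02469
eortc,mo,pf,0.06934
eortc,mo,rf,0.01498
eortc,mo,ghs,0.01767
eortc,sc,intercept1,-4.24535
eortc,sc,intercept2,-2.56552
eortc,sc,intercept3,-1.23110
eortc,sc,intercept4,0.17985
eortc,sc,female,0.60145
eortc,sc,pf,0.06035
eortc,sc,rf,0.01912
eortc,ua,intercept1,-9.28712
eortc,ua,intercept2,-6.21474
eortc,ua,intercept3,-4.16801
eortc,ua,intercept4,-1.46187
eortc,ua,female,0.33291
eortc,ua,pf,0.04812
eortc,ua,rf,0.03914
eortc,ua,sf,0.00770
eortc,ua,ghs,0.02419
eortc,pd,intercept1,-0.82400
eortc,pd,intercept2,2.75434
eortc,pd,intercept3,5.35925
eortc,pd,intercept4,7.64850
eortc,pd,ghs,0.02343
eortc,pd,pa,-0.07683
eortc,ad,intercept1,-6.65962
eortc,ad,intercept2,-4.31221
eortc,ad,intercept3,-2.81811
eortc,ad,intercept4,-0.86976
eortc,ad,age,0.02119
eortc,ad,ef,0.06947
factg,logistic,intercept,-11.54143
factg,logistic,pwb,0.34876
factg,logistic,ewb,0.06963
factg,logistic,fwb,0.04585
factg,beta,intercept,-0.65502
factg,beta,age,-0.01111
factg,beta,pwb,0.09845
factg,beta,ewb,0.03355
factg,beta,fwb,0.03922
factg,beta,scale,6.05147
factg,mo,intercept1,-1.86481
factg,mo,intercept2,-0.17843
factg,mo,intercept3,1.19513
factg,mo,intercept4,3.02125
factg,mo,age,-0.04819
factg,mo,pwb,0.21038
factg,mo,fwb,0.05296
factg,sc,intercept1,-0.47810
factg,sc,intercept2,0.85700
factg,sc,intercept3,1.83808
factg,sc,intercept4,2.87152
factg,sc,age,-0.04255
factg,sc,pwb,0.19205
factg,sc,fwb,0.07714
factg,ua,intercept1,-5.51844
factg,ua,intercept2,-3.04179
factg,ua,intercept3,-1.60687
factg,ua,intercept4,0.22225
factg,ua,age,-0.02439
factg,ua,pwb,0.26197
factg,ua,fwb,0.08561
factg,pd,intercept1,-5.90937
factg,pd,intercept2,-3.06146
factg,pd,intercept3,-1.28905
factg,pd,intercept4,0.45253
factg,pd,pwb,0.24215
factg,pd,fwb,0.01740
factg,ad,intercept1,-6.77040
factg,ad,intercept2,-4.14108
factg,ad,intercept3,-2.67943
factg,ad,intercept4,-0.88517
factg,ad,age,0.01664
factg,ad,pwb,0.04892
factg,ad,ewb,0.26968
factg,ad,fwb,0.04819
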