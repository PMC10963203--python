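domain,Na,N1a,N2a,Ya,Y1a,Y2a,Xa,X1a,X2a
1,48,34,14,142613,101034.6,41578.45,79618,56477.09,23140.91
2,32,22,10,79960,54976.49,24983.51,42145,28974.45,13170.55
3,38,27,11,110790,78626.42,32163.58,73633,52447.71,21185.29
4,41,29,12,89188,63072.35,26115.65,45090,31919.81,13170.19
5,15,10,5,54727,36483.44,18243.56,23008,15322.23,7685.77
6,29,20,9,65804,45356.59,20447.41,30631,21187.13,9443.86
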