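run,class,x_pH,x_temperature,x_time,X_pH,X_temperature,X_time,y_mean,y_se,n_rep,letters
1,factorial,1.0,1.0,-1.0,7.0,30.0,4.0,76.0,0.88,3,d
2,center,0.0,0.0,0.0,6.0,26.0,5.0,93.0,0.57,3,g
3,axial,0.0,0.0,-1.68,6.0,26.0,3.3200000000000003,75.0,1.1,3,d
4,center,0.0,0.0,0.0,6.0,26.0,5.0,93.0,1.7,3,g
5,factorial,1.0,-1.0,-1.0,7.0,22.0,4.0,69.0,0.57,3,b
6,factorial,-1.0,-1.0,-1.0,5.0,22.0,4.0,64.0,0.57,3,a
7,center,0.0,0.0,0.0,6.0,26.0,5.0,94.5,0.28,3,ghi
8,center,0.0,0.0,0.0,6.0,26.0,5.0,95.5,0.28,3,hi
9,factorial,-1.0,1.0,-1.0,5.0,30.0,4.0,73.0,0.0,3,c
10,center,0.0,0.0,0.0,6.0,26.0,5.0,95.6,0.57,3,i
11,axial,-1.68,0.0,0.0,4.32,26.0,5.0,76.0,0.57,3,d
12,center,0.0,0.0,0.0,6.0,26.0,5.0,93.5,0.57,3,gh
13,center,0.0,0.0,0.0,6.0,26.0,5.0,93.0,0.57,3,g
14,axial,0.0,1.68,0.0,6.0,32.72,5.0,75.0,0.57,3,d
15,factorial,-1.0,1.0,1.0,5.0,30.0,6.0,79.0,0.57,3,e
16,center,0.0,0.0,0.0,6.0,26.0,5.0,94.3,0.03,3,ghi
17,factorial,-1.0,-1.0,1.0,5.0,22.0,6.0,85.0,0.0,3,f
18,axial,0.0,0.0,1.68,6.0,26.0,6.68,85.2,0.11,3,f
19,factorial,1.0,1.0,1.0,7.0,30.0,6.0,71.0,0.6,3,c
20,axial,0.0,-1.68,0.0,6.0,19.28,5.0,75.0,0.0,3,d
21,factorial,1.0,-1.0,1.0,7.0,22.0,6.0,85.0,0.0,3,f
22,center,0.0,0.0,0.0,6.0,26.0,5.0,95.3,0.57,3,hi
23,axial,1.68,0.0,0.0,7.68,26.0,5.0,75.0,0.57,3,d
24,center,0.0,0.0,0.0,6.0,26.0,5.0,94.5,0.28,3,ghi
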