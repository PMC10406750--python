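row,name,region,base,family,distance,window,reported_p,cc_importance,mlo_importance
1,ROI_Std_Correlation_3,ROI,Correlation,GLCM,3,,0.000,0.47,2.03
2,ROI_Std_Difference_entropy_3,ROI,Difference_entropy,GLCM,3,,0.169,0.5,0.29
3,ROI_Std_Dissimilarity_3,ROI,Dissimilarity,GLCM,3,,0.245,0.14,0.11
4,ROI_Std_Difference_variance_3,ROI,Difference_variance,GLCM,3,,0.690,0,0.27
5,ROI_Std_Energy_3,ROI,Energy,GLCM,3,,0.025,0,0.37
6,ROI_Std_Entropy_3,ROI,Entropy,GLCM,3,,0.022,0.28,0
7,ROI_Std_Homogeneity_3,ROI,Homogeneity,GLCM,3,,0.343,0,1.10
8,ROI_Std_Information_measure_of_correlation1_3,ROI,Information_measure_of_correlation1,GLCM,3,,0.870,0,0
9,ROI_Std_Information_measure_of_correlation2_3,ROI,Information_measure_of_correlation2,GLCM,3,,0.582,0,0.17
10,ROI_Std_Maximum_probability_3,ROI,Maximum_probability,GLCM,3,,0.029,0,0.03
11,ROI_Std_Sum_entropy_3,ROI,Sum_entropy,GLCM,3,,0.000,1.25,0.5
12,ROI_Std_Sum_variance_3,ROI,Sum_variance,GLCM,3,,0.649,0.25,0.36
13,ROI_Std_Coarseness_3,ROI,Coarseness,NGTDM,,3,0.945,0,0.13
14,ROI_Std_Cluster_prominence_3,ROI,Cluster_prominence,GLCM,3,,0.398,0.69,0.4
15,ROI_Std_Cluster_shade_3,ROI,Cluster_shade,GLCM,3,,0.373,0.18,0
16,ROI_Std_Range_all,ROI,Range_all,FOS,,,0.006,0.68,0.15
17,ROI_Std_Sum_of_squares_variance_9,ROI,Sum_of_squares_variance,GLCM,9,,0.215,0,0.12
18,SQ_Correlation_9,SQ,Correlation,GLCM,9,,0.006,0.31,0.46
19,SQ_Difference_entropy_9,SQ,Difference_entropy,GLCM,9,,0.000,0,0
20,SQ_Dissimilarity_9,SQ,Dissimilarity,GLCM,9,,0.000,0.05,0.11
21,SQ_Difference_variance_9,SQ,Difference_variance,GLCM,9,,0.000,0.94,0
22,SQ_Energy_9,SQ,Energy,GLCM,9,,0.000,0.33,0.28
23,SQ_Entropy_9,SQ,Entropy,GLCM,9,,0.000,0.07,0.47
24,SQ_Homogeneity_9,SQ,Homogeneity,GLCM,9,,0.000,0,0
25,SQ_Information_measure_of_correlation1_9,SQ,Information_measure_of_correlation1,GLCM,9,,0.000,0.51,0.03
26,SQ_Information_measure_of_correlation2_9,SQ,Information_measure_of_correlation2,GLCM,9,,0.000,0.3,0.46
27,SQ_Maximum_probability_9,SQ,Maximum_probability,GLCM,9,,0.000,0.63,0
28,SQ_Sum_entropy_9,SQ,Sum_entropy,GLCM,9,,0.001,0.48,0.19
29,SQ_Sum_variance_9,SQ,Sum_variance,GLCM,9,,0.000,0.11,0.13
30,SQ_Coarseness_9,SQ,Coarseness,NGTDM,,9,0.535,0.77,1.03
31,SQ_Cluster_prominence_9,SQ,Cluster_prominence,GLCM,9,,0.511,0.02,0
32,SQ_Cluster_shade_9,SQ,Cluster_shade,GLCM,9,,0.182,0.22,0.54
33,SQ_Range_all,SQ,Range_all,FOS,,,0.000,1.57,0.31
34,SQ_Sum_of_squares_variance_9,SQ,Sum_of_squares_variance,GLCM,9,,0.000,0,0
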