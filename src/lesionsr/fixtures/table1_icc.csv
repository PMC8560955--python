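feature_id,feature,Original,Bicubic,GAN-SR
#1,GLCM_Correlation,0.980,0.979,0.984
#2,GLCM_DifferenceEntropy,0.846,0.911,0.910
#3,GLCM_Idmn,0.996,0.996,0.997
#4,GLCM_Idn,0.997,0.995,0.998
#5,GLCM_MCC,0.633,0.938,0.923
#6,GLCM_SumEntropy,0.822,0.897,0.905
#7,GLRLM_LongRunLowGrayLevelEmphasis,0.926,0.560,0.631
#8,GLRLM_LowGrayLevelRunEmphasis,0.967,0.952,0.944
#9,GLRLM_ShortRunLowGrayLevelEmphasis,0.970,0.973,0.925
#10,GLDM_DependenceEntropy,0.910,0.870,0.895
#11,GLDM_LargeDependenceLowGrayLevelEmphasis,0.985,0.976,0.890
#12,GLDM_LowGrayLevelEmphasis,0.986,0.986,0.950
#13,GLDM_SmallDependenceLowGrayLevelEmphasis,0.902,0.955,0.946
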