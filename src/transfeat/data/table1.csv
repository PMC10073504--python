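signal,feature,method,marker
ECG,SDNN_ECG,M1,*
ECG,RMSSD_ECG,M1,*
ECG,MEANRR_ECG,M1,*(—)
ECG,NN50_ECG,M1,*
ECG,PNN50_ECG,M1,*(—)
ECG,MSE1_ECG,M1,—
ECG,MSE2_ECG,M1,—
ECG,MSE3_ECG,M1,*
ECG,MSE4_ECG,M1,*
ECG,MSE5_ECG,M1,—
ECG,HR_ECG,M1,*(—)
ECG,VLF_ECG,M1,*
ECG,LF_ECG,M1,*(—)
ECG,HF_ECG,M1,*(—)
ECG,LF_HF_ECG,M1,*
BVP,SDNN_BVP,M1,*
BVP,RMSSD_BVP,M1,*
BVP,MEANRR_BVP,M1,*(—)
BVP,LF_BVP,M1,*
BVP,HF_BVP,M1,—
BVP,WIDTH_BVP,M1,—
BVP,HIGH_BVP,M1,*
BVP,H_W_BVP,M1,*
BVP,MAXPA_BVP,M1,*
BVP,STDPA_BVP,M1,*(—)
BVP,MEANPA_BVP,M1,*(—)
BVP,PR_BVP,M1,*(—)
GSR,MEANT_GSR,M1,*
GSR,STDT_GSR,M1,—
GSR,AUCT_GSR,M1,*
GSR,STDR_GSR,M1,*
GSR,AUCR_GSR,M1,*
GSR,NUMP_GSR,M1,*
GSR,MAXPA_GSR,M1,*
GSR,MEANPA_GSR,M1,*(—)
GSR,STDPA_GSR,M1,*(—)
GSR,MEANPR_GSR,M1,*
GSR,STDPR_GSR,M1,*
GSR,PSD_GSR,M1,*
ECG,SDNN_ECG,M3,*
ECG,RMSSD_ECG,M3,—
ECG,MEANRR_ECG,M3,—
ECG,NN50_ECG,M3,*
ECG,PNN50_ECG,M3,—
ECG,MSE1_ECG,M3,—
ECG,MSE2_ECG,M3,—
ECG,MSE3_ECG,M3,—
ECG,MSE4_ECG,M3,—
ECG,MSE5_ECG,M3,—
ECG,HR_ECG,M3,*
ECG,VLF_ECG,M3,—
ECG,LF_ECG,M3,*
ECG,HF_ECG,M3,*(—)
ECG,LF_HF_ECG,M3,*
BVP,SDNN_BVP,M3,*
BVP,RMSSD_BVP,M3,*
BVP,MEANRR_BVP,M3,—
BVP,LF_BVP,M3,—
BVP,HF_BVP,M3,—
BVP,WIDTH_BVP,M3,—
BVP,HIGH_BVP,M3,—
BVP,H_W_BVP,M3,*
BVP,MAXPA_BVP,M3,*
BVP,STDPA_BVP,M3,—
BVP,MEANPA_BVP,M3,*(—)
BVP,PR_BVP,M3,—
GSR,MEANT_GSR,M3,*
GSR,STDT_GSR,M3,—
GSR,AUCT_GSR,M3,—
GSR,STDR_GSR,M3,*
GSR,AUCR_GSR,M3,—
GSR,NUMP_GSR,M3,—
GSR,MAXPA_GSR,M3,*
GSR,MEANPA_GSR,M3,*(—)
GSR,STDPA_GSR,M3,*(—)
GSR,MEANPR_GSR,M3,—
GSR,STDPR_GSR,M3,*
GSR,PSD_GSR,M3,—
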