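# Published cross-dataset improvement comparisons of PA OmniNet against U-net
# baselines on the OADAT, in vivo mouse and vascular phantom benchmarks.
# Columns: ssim_pct = relative SSIM gain (%), rmse_pct = relative RMSE
# reduction (%), psnr_db = absolute PSNR difference (dB); positive means the
# first-named model is better.
comparison,dataset,ssim_pct,rmse_pct,psnr_db
generalized_vs_unet_generalized,OADAT SWFD Semi,2.26,23.23,2.70
generalized_vs_unet_generalized,OADAT SWFD Multi,4.47,14.69,1.70
generalized_vs_unet_generalized,OADAT MSFD,5.28,22.10,2.40
generalized_vs_unet_generalized,OADAT SCD,30.49,55.99,6.41
generalized_vs_unet_generalized,Mouse 16 sparse,6.89,0.40,0.12
generalized_vs_unet_generalized,Mouse 32 sparse,4.96,7.43,1.06
generalized_vs_unet_generalized,Mouse 64 sparse,6.19,23.92,2.78
generalized_vs_unet_generalized,Mouse 128 sparse,6.92,20.40,2.31
generalized_vs_unet_generalized,Vascular Phantom 16 sparse,7.09,-35.50,-2.53
generalized_vs_unet_generalized,Vascular Phantom 32 sparse,8.41,-16.86,-1.42
specific_vs_unet_specific,OADAT SWFD Multi,7.06,19.55,2.08
specific_vs_unet_specific,OADAT MSFD,3.13,19.16,2.06
specific_vs_unet_specific,OADAT SCD,1.98,22.06,2.30
specific_vs_unet_specific,Mouse 16 sparse,37.77,69.70,11.22
specific_vs_unet_specific,Mouse 32 sparse,14.36,27.62,2.62
specific_vs_unet_specific,Mouse 64 sparse,10.01,33.06,3.64
specific_vs_unet_specific,Mouse 128 sparse,2.46,19.45,1.78
specific_vs_unet_specific,Vascular Phantom 16 sparse,36.01,67.72,10.58
specific_vs_unet_specific,Vascular Phantom 32 sparse,11.28,-2.53,-0.46
generalized_vs_unet_specific,OADAT SWFD Multi,3.92,15.91,1.78
generalized_vs_unet_specific,OADAT MSFD,-0.91,7.75,0.87
generalized_vs_unet_specific,OADAT SCD,-1.12,-35.45,-2.28
generalized_vs_unet_specific,Mouse 16 sparse,24.64,70.65,11.67
generalized_vs_unet_specific,Mouse 32 sparse,7.84,24.39,2.27
generalized_vs_unet_specific,Mouse 64 sparse,8.10,36.31,4.08
generalized_vs_unet_specific,Mouse 128 sparse,-0.68,-13.26,-0.75
generalized_vs_unet_specific,Vascular Phantom 16 sparse,24.53,61.86,8.85
generalized_vs_unet_specific,Vascular Phantom 32 sparse,6.32,-5.41,-0.66
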