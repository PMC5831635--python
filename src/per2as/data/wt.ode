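# XPPAUT-style parameter declarations for the wild-type clock model.
# Mirrors data/wt.params; read with per2as.parse_ode_parameters.
par V1max=1.0, V2max=1.0, V3max=1.577, V4max=0.8238
par V5max=1.0, a=12.0, a2=10.0, a3=7.0
par a4=5.805, a5=8.0, b=10.2057, c=5.6015
par b2=4.787, c2=6.052, b3=5.278, c3=4.0
par b4=6.0, c4=4.0, b5=1.26, c5=2.656
par Kt1=1.3665, Kt2=0.9107, Kt3=0.7952, Kt4=1.0
par Kt5=9.354, Ki1=0.9154, Ki2=1.0, Ki3=1.5
par Ki4=1.5, Ki5=6.22, Ki6=8.126, c6=7.771
par d_y1=0.3, d_y2=0.1902, d_y3=2.0, d_y4=0.3783
par d_y5=0.8137, k_p1=0.3763, k_p2=0.6167, k_p3=1.0885
par k_p4=0.5001, k_p5=0.4842, k_ph=1.1409, k_dph=0.03871
par k_f1=0.09795, k_d1=0.04989, k_f2=0.3247, k_d2=0.03191
par k_im1=0.3736, k_ex1=0.00534, k_im2=0.344, k_ex2=0.00534
par k_im3=0.06368, k_im4=0.3, k_im5=0.3, k_act=0.2817
par k_deact=0.1, d_x1=0.3863, d_x2=0.05825, d_x3=0.08481
par d_x4=0.05521, d_x5=0.08645, d_x6=0.2, d_x7=0.1886
par d_x8=0.1471, d_x9=0.06813, d_x10=0.4205, d_x11=0.03296
par d_x12=0.04956, d_x13=0.09156, d_x14=0.09156, mu=1.0
par lam=1.0, lam0=0.2, lam1=1.0, K_S=0.15
par K_AS=10.0, d_AS=2.5, k_assn=0.1, k_diss=0.1
par d_dup=0.1
done
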