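name,CAS,phase,phi0,A,err_A,B,err_B,C,err_C,Tchar_C,err_Tchar,thetachar,err_thetachar,dCp,err_dCp,dHref,err_dHref,dSref,err_dSref,Tref_C,N,category,source,flag,flag_reason
cinnamaldehyde,104-55-2,Rxi17SilMS,0.001,-82.062,0.65699,10505,41.611,10.503,0.092476,,,,,,,,,,,90,,fragrances,example,False,
farnesol A,4602-84-0,Rxi17SilMS,0.001,-108.94,5.955,13698,402.29,13.933,0.82925,,,,,,,,,,,90,,fragrances,example,False,
farnesol B,4602-84-0,Rxi17SilMS,0.001,-143.29,4.9454,15819,337.2,18.806,0.68763,,,,,,,,,,,90,,fragrances,example,False,
geraniol,106-24-1,Rxi17SilMS,0.001,-88.825,2.3832,10625,143.78,11.451,0.33807,,,,,,,,,,,90,,fragrances,example,False,
glyceryl tridecanoate,621-71-6,Rxi17SilMS,0.001,-394.74,65.672,41657,5590.7,51.841,8.818,,,,,,,,,,,90,,triglycerides,example,False,
glyceryl trihexanoate,621-70-5,Rxi17SilMS,0.001,-188.84,20.96,22064,1588.2,24.456,2.8654,,,,,,,,,,,90,,triglycerides,example,False,
glyceryl trilaurate,538-24-9,Rxi17SilMS,0.001,-543.67,127.33,55893,11394,71.568,16.969,,,,,,,,,,,90,,triglycerides,example,False,
glyceryl trimyristin,555-45-3,Rxi17SilMS,0.001,-655.14,198.66,66369,27435,86.428,25.872,,,,,,,,,,,90,,triglycerides,example,False,
glyceryl trioctanoate,538-23-8,Rxi17SilMS,0.001,-211.38,27.344,25948,2197.4,27.112,3.7033,,,,,,,,,,,90,,triglycerides,example,False,
glyceryl tripalmitin,555-44-2,Rxi17SilMS,0.001,-493.02,661.79,53703,529250,64.545,23.508,,,,,,,,,,,90,,triglycerides,example,False,
iso E super A,54464-57-2,Rxi17SilMS,0.001,-94.965,2.4567,12303,167.07,12.154,0.34177,,,,,,,,,,,90,,fragrances,example,False,
iso E super B,54464-57-2,Rxi17SilMS,0.001,-96.736,3.5892,12420,243.95,12.407,0.49917,,,,,,,,,,,90,,fragrances,example,False,
iso E super C,54464-57-2,Rxi17SilMS,0.001,-96.021,5.507,12334,376.07,12.331,0.76535,,,,,,,,,,,90,,fragrances,example,False,
iso E super D,54464-57-2,Rxi17SilMS,0.001,-101.18,5.3862,12802,368.57,13.014,0.74834,,,,,,,,,,,90,,fragrances,example,False,
limonene,138-86-3,Rxi17SilMS,0.001,-75.098,4.3818,8393.5,240.6,9.8499,0.63146,,,,,,,,,,,90,,fragrances,example,False,
linalool,78-70-6,Rxi17SilMS,0.001,-83.176,2.6778,9508.6,151.66,10.803,0.38383,,,,,,,,,,,90,,fragrances,example,False,
PCB 101,37680-73-2,Rxi5SilMS,0.002,-111.16,0.85969,14804,66.924,14.179,0.11708,,,,,,,,,,,90,,PCBs,example,False,
PCB 138,35065-28-2,Rxi5SilMS,0.002,-107.39,2.4739,15187,200.61,13.561,0.33499,,,,,,,,,,,90,,PCBs,example,False,
PCB 153,35065-27-1,Rxi5SilMS,0.002,-106.02,3.2438,14985,260.39,13.377,0.43993,,,,,,,,,,,90,,PCBs,example,False,
PCB 180,35065-29-3,Rxi5SilMS,0.002,-95.041,5.9211,14747,489.4,11.783,0.79956,,,,,,,,,,,90,,PCBs,example,False,
PCB 28,7012-37-5,Rxi5SilMS,0.002,-101.55,2.2747,13300,169.51,13.001,0.31176,,,,,,,,,,,90,,PCBs,example,False,
PCB 52,35693-99-3,Rxi5SilMS,0.002,-108.61,2.3285,14057,175.54,13.925,0.31859,,,,,,,,,,,90,,PCBs,example,False,
benz[a]anthracene,56-55-3,ZB-PAH-CT,0.001,-17.543,48.568,9795.2,3816.2,0.92277,6.6114,,,,,,,,,,,90,,PAHs,example,False,
benzo[ghi]perylene,191-24-2,ZB-PAH-CT,0.001,-15.308,13.044,10841,1125.3,0.57344,1.7504,,,,,,,,,,,90,,PAHs,example,False,
dibenzo[ah]anthracene,53-70-3,ZB-PAH-CT,0.001,-93.497,26.461,16475,2300.0,11.327,3.5481,,,,,,,,,,,90,,PAHs,example,False,
indeno[123cd]pyrene,193-39-5,ZB-PAH-CT,0.001,-55.231,39.696,13583,3436.5,6.0911,5.3263,,,,,,,,,,,90,,PAHs,example,False,
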