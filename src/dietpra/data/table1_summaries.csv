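region,n,mean,sd,median,max
Changhua,210,0.03,0.03,0.03,0.16
Chiayi,138,0.03,0.02,0.02,0.12
Hsinchu,102,0.06,0.04,0.04,0.17
Hualien,115,0.03,0.02,0.03,0.10
Kaohsiung,96,0.03,0.03,0.02,0.14
Keelung,39,0.05,0.04,0.04,0.24
Miaoli,76,0.05,0.02,0.04,0.12
Nantou,32,0.07,0.03,0.04,0.13
New Taipei,40,0.04,0.04,0.04,0.15
Pingtung,73,0.03,0.02,0.05,0.13
Taichung,120,0.07,0.03,0.04,0.22
Tainan,90,0.03,0.04,0.02,0.25
Taipei,40,0.05,0.08,0.04,0.37
Taitung,75,0.02,0.02,0.03,0.07
Taoyuan,95,0.08,0.06,0.05,0.39
Yilan,69,0.10,0.08,0.03,0.27
Yunlin,171,0.04,0.03,0.04,0.22
Total,1581,0.04,0.04,0.03,0.39
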