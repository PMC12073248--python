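no,name,formula,adducts,rt_min,fragments,reference_mz,reference_experimental_mz,reference_ppm,reference_dbe
1,Gluconic acid,C6H12O7,[M-H]-,7.0514,177.0404;129.0192;99.0091;75.0097,195.0510,195.0523,-6.5,1
2,Quinic acid,C7H12O6,[M-H]-,8.078,173.0555;127.0475;103.0099,191.0561,191.0563,-0.98,2
3,Malic acid,C4H6O5,[M-H]-,9.587,114.9936;89.0169;71.0086,133.0142,133.0148,-4.12,2
4,Citric acid,C6H8O7,[M-H]-,10.459,173.0064;129.0168;111.0068;87.0074,191.0197,191.0198,-0.38,3
5,Baicalin,C21H18O11,[M-H]-,17.618,,445.0776,445.0788,-2.61,13
6,Protocatechuoylglucose,C13H16O9,[M-H]-,21.609,203.0012;165.0184;152.0111;108.0214,315.0722,315.0731,-2.99,6
7,Glucogallic acid,C13H16O10,[M-H]-,21.860,313.0577;168.0061;125.0238,331.0671,331.0673,-0.69,6
8,Dihydroferulic acid 4-O-glucuronide,C16H20O10,[M-H]-,22.917,251.0550;209.0314;197.0468;191.0258;167.0335,371.0984,371.0988,-1.15,7
9,Chlorogenic acid,C16H18O9,[M-H]-,23.068,209.0299;191.0557;179.0349;161.0232;135.0444,353.0872,353.0882,-1.11,8
10,Dihydroxybenzoic acid,C7H6O4,[M-H]-,23.4,109.0292;81.0350,153.0193,153.0195,-1.09,5
11,Protocatechuic acid,C7H6O4,[M-H]-,23.403,109.0293;91.0189;81.0352,153.0212,153.0198,-3.4,5
12,Isopropylmalic acid,C7H12O5,[M-H]-,24.845,157.0456;131.0659;115.0352,175.0612,175.0606,3.39,2
13,Neochlorogenic acid,C16H18O9,[M-H]-,25.164,191.0529;179.0312;173.0426;161.0211,353.0872,353.0856,6.23,8
14,Syringetin glucoside,C23H24O13,[M-H]-,25.248,,507.1144,507.1150,-1.15,12
15,Feruloyl hexose,C16H20O9,[M-H]-,25.751,193.0499;149.0594;134.0358,355.1034,355.1040,-1.53,7
16,Syringin,C17H24O9,[M-H]-,25.919,209.0647;191.0683;179.0515;149.0459,371.1348,371.1353,-1.46,6
17,Feruloyl-glucose isomers,C16H20O9,[M-H]-,26.003,241.1059;193.0494;149.0598;134.0364,355.1029,355.1042,-2.09,7
18,Ferulic acid,C10H10O4,[M-H]-,26.103,149.0592;134.0363,193.0506,193.0513,-3.44,6
19,(Z)-chlorogenic acid,C16H18O9,[M-H]-,26.1870,191.0550;161.0235;149.0595;134.0360;119.0337,353.0872,353.0875,-4.78,8
20,p-Coumaroyltartaric acid,C13H14O7,[M-H]-,26.606,,281.0667,281.0647,7.01,7
21,"7,8-Dihydroxycoumarin",C9H6O4,[M-H]-,27.009,149.0202;133.0257;105.0311,177.0193,177.0193,0.18,7
22,Esculetin,C9H6O4,[M-H]-,27.076,149.0209;133.0251;121.0247;105.0310,177.0193,177.0202,-4.87,7
23,Apigenin-7-O-rhamnoglucoside (Rhoifolin),C27H30O14,[M-H]-,27.260,413.0882;293.0461,577.1563,577.1568,-0.9,13
24,Caffeic acid,C9H8O4,[M-H]-,27.361,163.0052;135.0444;93.0340,179.0350,179.0357,-3.99,6
25,Luteolin-7-O-rutinoside,C27H30O15,[M-H]-,27.746,285.0401,593.1506,593.1534,-3.71,13
26,Caffeoylmalic acid,C13H12O8,[M-H]-,28.233,179.0343;163.0365;133.0135;115.0026,295.0459,295.0478,-6.28,8
27,4-Methylumbelliferone,C10H8O3,[M+H]+,28.308,149.0590;133.0647;121.0651,177.0546,177.0554,-4.43,7
28,Luteolin galactoside,C21H20O11,[M-H]-,28.669,327.0514;285.0396;256.0364;151.0020,447.0933,447.0934,-0.26,12
29,Kaempferol glucoside,C21H20O11,[M-H]-,28.669,285.0396,447.0934,447.0933,0.26,12
30,Patulitrin,C22H22O13,[M-H]-,28.719,331.0447;316.0209;287.0193;181.0126,493.0990,493.0988,0.48,12
31,Glucocaffeic acid,C15H18O9,[M-H]-,28.736,281.0611;251.0487;179.0297;161.0204;135.0398,341.0881,341.0891,-3.78,7
32,Hyperoside,C21H20O12,[M-H]-,28.736,300.0274;271.0225;151.0012,463.0891,463.0896,-3.02,12
33,Propylglutaric acid,C8H14O4,[M-H]-,29.189,,173.0819,173.0809,5.93,2
34,Hydroxydecanoic acid,C10H18O5,[M-H]-,29.574,199.0939;171.1004;155.1064;137.0957;127.1105,217.1081,217.1076,2.51,2
35,Di-caffeoylquinic acid I,C25H24O12,[M-H]-,29.776,353.0854;335.0794;308.1009;191.0540;179.0340;173.0435,515.1195,515.1203,-1.55,14
36,Isorhamnetin 3-O-glucoside,C22H22O12,[M-H]-,30.262,315.0617;299.0130;285.0347;243.0349;161.0189;152.0057;108.0163,477.1053,477.1038,3.03,12
37,"Kaempferol 3-(6''-malonylglucoside)",C24H22O14,[M-H]-,30.396,489.1002;285.0350;150.9987,533.0950,533.0937,2.47,14
38,Sinapic acid,C11H12O5,[M-H]-,30.447,179.0651;163.0362;133.0623,223.0612,223.0604,3.56,6
39,Apigenin 8-C-glucoside,C21H20O10,[M-H]-,30.530,268.0321,431.0984,431.0964,4.56,12
40,Di-caffeoyl-quinic acid II,C25H24O12,[M-H]-,30.933,353.0854;191.0533;179.0325;173.0424;161.0240;135.0435,515.1205,515.1195,1.94,14
41,Di-caffeoylquinic acid III,C25H24O12,[M-H]-,31.117,353.0880;323.0773;191.0549;179.0337;173.0441;161.0237,515.1195,515.1196,-0.19,14
42,Kaempferol-3-O-alpha-L-arabinoside,C20H18O10,[M-H]-,31.537,,417.0827,417.0849,-5.21,12
43,Apigenin,C15H10O5,[M-H]-,31.620,,269.0455,269.0462,-2.42,11
44,Luteolin,C15H10O6,[M-H]-,32.62,,285.0405,285.0419,-5.03,11
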