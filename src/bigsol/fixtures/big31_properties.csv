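id,name,log_s0,sd,n_sources,mw,mp,clogp,dh_sol,nha,nhd,nrot,A,B,S_pi,E,V,ionization
amphotericin-b,Amphotericin B,-3.52,0.69,2,924,179,0.71,-33,17,12,3,3.55,5.99,5.12,4.47,7.12,ampholyte
anidulafungin,Anidulafungin,-4.36,0.45,,1140,250,-0.93,0,17,14,14,3.67,8.22,10.4,7.8,8.4,neutral
bryamycin,Bryamycin,-4.14,0.29,3,1665,210,0.77,-16,31,17,12,4.47,11.56,14.55,10.51,11.65,ampholyte
cyclosporine-a,Cyclosporine A,-5.03,0.16,6,1203,151,3.27,-40,12,5,15,1.25,7.61,10.16,4.23,10.02,neutral
dactinomycin,Dactinomycin,-3.22,0.16,2,1255,242,0.73,-10,18,5,8,1.36,8.49,11.45,6.12,9.49,neutral
docetaxel,Docetaxel,-5.14,0.05,2,808,232,3.26,-12,14,5,8,1.03,4.01,4.18,3.47,5.92,neutral
everolimus,Everolimus,-5.02,0.58,,958,138,6.20,-36,14,3,9,0.63,4.73,4.73,3.29,7.68,neutral
gramicidin-a,Gramicidin A,-4.16,0.41,,1882,229,4.37,-31,17,21,53,5.57,11.3,17.8,10.26,14.81,neutral
gramicidin-s,Gramicidin S,-3.89,0.35,,1141,169,1.23,-14,12,10,16,2.46,7.42,10.69,5.38,9.12,ampholyte
iodipamide,Iodipamide,-5.47,0.67,,1140,307,6.85,45,4,4,9,2.25,1.87,4.84,5.86,4.38,acid
iodoxamic-acid,Iodoxamic Acid,-5.49,0.36,,1288,224,6.13,35,8,4,19,2.25,2.73,5.48,6.01,5.46,acid
ivermectin,Ivermectin,-5.56,0.39,5,875,140,5.60,-33,14,3,8,0.68,4.23,3.21,3.24,6.72,neutral
leuprolide,Leuprolide,-3.15,0.20,,1209,153,-1.44,-11,14,15,32,4.25,8.66,11.75,7.23,9.21,ampholyte
nafarelin,Nafarelin,-5.61,0.52,,1323,189,-1.62,2,15,16,33,4.74,9.32,13.46,8.93,9.88,ampholyte
nystatin,Nystatin,-4.1,0.39,,926,170,0.94,-35,17,12,3,3.55,5.93,5.02,4.32,7.16,ampholyte
oxytocin,Oxytocin,-1.2,0.17,,1007,164,-3.61,2,15,12,17,3.96,7.67,11.34,5.9,7.47,ampholyte
paclitaxel,Paclitaxel,-6.53,0.14,2,854,216,3.74,-3,14,4,10,0.9,4.13,5.22,4.05,6.2,neutral
paclitaxel-analog12,Paclitaxel analog12,-5.48,0.67,,808,187,3.20,-14,14,5,8,1.03,4.01,4.18,3.47,5.92,neutral
paclitaxel-analog17,Paclitaxel analog17,-4.52,0.48,,802,179,3.32,-24,14,5,9,1.03,3.97,3.67,2.87,6.02,neutral
paclitaxel-analog23,Paclitaxel analog23,-5.78,0.73,,807,187,3.23,-13,13,6,8,1.33,4.15,4.31,3.63,5.96,neutral
rapamycin,Rapamycin,-5.55,0.69,,914,184,6.18,-30,13,3,6,0.63,4.51,4.57,3.26,7.34,neutral
rifabutin,Rifabutin,-4.09,0.66,3,847,176,4.62,-9,14,5,4,1.31,4.39,4.43,4.24,6.47,ampholyte
rifampicin,Rifampicin,-2.96,0.27,9,823,164,4.34,-6,15,6,4,2.55,4.66,4.67,4.73,6.21,ampholyte
roxithromycin,Roxithromycin,-3.98,0.37,,837,120,2.21,-47,17,5,13,1.05,5.12,2.9,2.58,6.55,base
solithromycin,Solithromycin,-6.23,0.14,,845,189,4.60,-12,15,2,11,0.35,4.46,4.7,3.67,6.44,base
stevioside,Stevioside,-2.83,0.17,,805,198,-2.94,-21,18,11,9,2.74,5.49,4.29,4.25,5.67,neutral
tacrolimus,Tacrolimus,-5.42,0.54,2,804,126,4.64,-27,12,3,7,0.71,3.98,3.98,2.82,6.38,neutral
telithromycin,Telithromycin,-3.02,0.17,,812,188,4.93,-13,14,1,11,0.12,4.40,4.53,3.49,6.32,base
temsirolimus,Temsirolimus,-5.06,0.59,,1030,134,5.72,-39,16,4,10,1.02,5.07,5.25,3.46,8.17,neutral
ubiquinone,Ubiquinone,-7.56,1.65,2,863,48,17.85,-53,4,0,31,0.00,2.20,1.16,2.15,7.95,neutral
vancomycin,Vancomycin,-2.13,0.14,,1449,175,0.11,-22,25,19,13,5.81,10.56,12.32,9.73,9.88,ampholyte
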