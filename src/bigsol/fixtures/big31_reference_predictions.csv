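id,obs,gse,absolv,rfr,sebm
amphotericin-b,-3.52,-1.75,-4.86,-3.25,22
anidulafungin,-4.36,-0.82,-7.16,-4.30,628
bryamycin,-4.14,-2.12,-9.33,-3.90,156099
cyclosporine-a,-5.03,-4.03,-7.12,-4.65,123
dactinomycin,-3.22,-2.40,-7.07,-3.82,7080
docetaxel,-5.14,-4.83,-5.97,-4.86,7
everolimus,-5.02,-6.83,-7.25,-5.93,172
gramicidin-a,-4.16,-5.91,-14.26,-6.00,12667592811
gramicidin-s,-3.89,-2.17,-7.20,-3.78,2056
iodipamide,-5.47,-9.17,-10.11,-6.51,43888
iodoxamic-acid,-5.49,-7.62,-10.42,-5.96,85035
ivermectin,-5.56,-6.25,-6.48,-5.92,8
leuprolide,-3.15,0.67,-6.89,-3.84,5514
nafarelin,-5.61,0.48,-8.73,-4.24,1314
nystatin,-4.10,-1.89,-4.84,-3.16,5
oxytocin,-1.20,2.72,-4.57,-2.87,2350
paclitaxel,-6.53,-5.15,-7.00,-5.67,3
paclitaxel-analog12,-5.48,-4.32,-5.97,-4.84,3
paclitaxel-analog17,-4.52,-4.36,-5.44,-4.61,8
paclitaxel-analog23,-5.78,-4.35,-5.91,-4.98,1
rapamycin,-5.55,-7.27,-7.09,-6.05,35
rifabutin,-4.09,-5.63,-6.97,-5.65,765
rifampicin,-2.96,-5.23,-6.40,-5.47,2780
roxithromycin,-3.98,-2.66,-3.74,-3.76,1
solithromycin,-6.23,-5.74,-6.39,-5.76,1
stevioside,-2.83,1.71,-3.45,-2.22,4
tacrolimus,-5.42,-5.15,-6.01,-5.53,4
telithromycin,-3.02,-6.06,-6.15,-5.50,1340
temsirolimus,-5.06,-6.31,-7.54,-5.97,301
ubiquinone,-7.56,-17.58,-10.60,-6.59,1102
vancomycin,-2.13,-1.11,-6.97,-4.01,69548
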