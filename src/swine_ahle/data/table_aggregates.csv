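table,line,kind,units,average,top10,ideal,ideal_p5,ideal_p95
breeding,reared_piglets,revenue,chf,2895,3544,4816,,
breeding,cull_sow,revenue,chf,64,55,50,,
breeding,total_output,total,chf,2959,3600,4866,,
breeding,replacement,cost,chf,296,256,230,,
breeding,insemination,cost,chf,34,32,29,,
breeding,gestation_feed,cost,chf,505,497,496,,
breeding,lactation_feed,cost,chf,326,347,351,,
breeding,starter_feed,cost,chf,39,47,63,,
breeding,rearing_feed,cost,chf,591,638,780,,
breeding,gilt_feed,cost,chf,144,125,112,,
breeding,total_feed,total,chf,1604,1654,1803,,
breeding,veterinary,cost,chf,117,138,39,,
breeding,organizational,cost,chf,11,11,11,,
breeding,ear_tags,cost,chf,9,11,14,,
breeding,cleaning,cost,chf,13,13,13,,
breeding,transport,cost,chf,201,201,201,,
breeding,energy,cost,chf,50,50,50,,
breeding,water,cost,chf,6,6,6,,
breeding,straw,cost,chf,144,144,144,,
breeding,label_inspection,cost,chf,2,2,2,,
breeding,total_misc,total,chf,436,438,441,,
breeding,margin_sow_herd20,margin,chf,463,1073,2325,2207,2442
breeding,margin_sow_herd50,margin,chf,469,1079,2325,2207,2442
breeding,margin_sow_herd150,margin,chf,472,1082,2325,2207,2442
breeding,herd_year_20,herd_margin,kchf,9,21,46,44,49
breeding,herd_year_50,herd_margin,kchf,23,54,116,110,122
breeding,herd_year_150,herd_margin,kchf,71,162,349,331,366
fattening,total_output,total,chf,320,320,320,,
fattening,replacement,cost,chf,124,127,122,,
fattening,feed,cost,chf,137,124,111,,
fattening,veterinary,cost,chf,0.50,0.50,0,,
fattening,organizational,cost,chf,1,1,1,,
fattening,cleaning,cost,chf,6,6,6,,
fattening,transport,cost,chf,16,16,16,,
fattening,energy,cost,chf,3,3,3,,
fattening,water,cost,chf,1,1,1,,
fattening,straw,cost,chf,13,13,13,,
fattening,label_inspection,cost,chf,1,1,1,,
fattening,total_misc,total,chf,41,41,41,,
fattening,margin_pig,margin,chf,18,32,47,43,51
fattening,herd_year_150,herd_margin,kchf,9,16,26,23,28
fattening,herd_year_350,herd_margin,kchf,20,37,60,55,65
fattening,herd_year_1000,herd_margin,kchf,58,106,171,156,186
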