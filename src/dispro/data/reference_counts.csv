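drug,block,label,count,printed_percent
canagliflozin,total,Number of cases,2128,
dapagliflozin,total,Number of cases,361,
empagliflozin,total,Number of cases,1049,
ertugliflozin,total,Number of cases,2,
canagliflozin,sex,Male,1437,67.5
dapagliflozin,sex,Male,245,67.9
empagliflozin,sex,Male,698,66.5
ertugliflozin,sex,Male,2,100
canagliflozin,outcome,Hospitalization-initial or prolonged,1054,49.5
dapagliflozin,outcome,Hospitalization-initial or prolonged,140,38.8
empagliflozin,outcome,Hospitalization-initial or prolonged,422,40.2
ertugliflozin,outcome,Hospitalization-initial or prolonged,0,
canagliflozin,outcome,Life-threatening,29,1.4
dapagliflozin,outcome,Life-threatening,41,11.4
empagliflozin,outcome,Life-threatening,121,11.5
ertugliflozin,outcome,Life-threatening,0,
canagliflozin,outcome,Disability,427,20.1
dapagliflozin,outcome,Disability,51,14.1
empagliflozin,outcome,Disability,126,12.1
ertugliflozin,outcome,Disability,0,
canagliflozin,outcome,Death,27,1.2
dapagliflozin,outcome,Death,24,6.7
empagliflozin,outcome,Death,46,4.4
ertugliflozin,outcome,Death,0,
canagliflozin,outcome,Other medical events,591,27.8
dapagliflozin,outcome,Other medical events,105,29
empagliflozin,outcome,Other medical events,334,31.8
ertugliflozin,outcome,Other medical events,2,100
canagliflozin,region,North America,2041,95.7
dapagliflozin,region,North America,198,52.0
empagliflozin,region,North America,561,51.8
ertugliflozin,region,North America,2,100.0
canagliflozin,region,Europe,58,2.7
dapagliflozin,region,Europe,122,32.0
empagliflozin,region,Europe,346,32.0
ertugliflozin,region,Europe,0,
canagliflozin,region,Asia,29,1.4
dapagliflozin,region,Asia,36,9.4
empagliflozin,region,Asia,73,6.7
ertugliflozin,region,Asia,0,
canagliflozin,region,Oceania,2,0.1
dapagliflozin,region,Oceania,16,4.2
empagliflozin,region,Oceania,89,8.2
ertugliflozin,region,Oceania,0,
canagliflozin,region,South America,1,0.0
dapagliflozin,region,South America,8,2.1
empagliflozin,region,South America,11,1.0
ertugliflozin,region,South America,0,
canagliflozin,region,Africa,0,0.0
dapagliflozin,region,Africa,1,0.3
empagliflozin,region,Africa,2,0.2
ertugliflozin,region,Africa,0,
canagliflozin,region,Unknown,2,0.1
dapagliflozin,region,Unknown,0,0.0
empagliflozin,region,Unknown,0,0.0
ertugliflozin,region,Unknown,0,
canagliflozin,year,2015,1,0.0
dapagliflozin,year,2015,0,0.0
empagliflozin,year,2015,0,0.0
ertugliflozin,year,2015,0,
canagliflozin,year,2016,19,0.9
dapagliflozin,year,2016,1,0.3
empagliflozin,year,2016,3,0.3
ertugliflozin,year,2016,0,
canagliflozin,year,2017,144,6.8
dapagliflozin,year,2017,16,4.4
empagliflozin,year,2017,20,1.9
ertugliflozin,year,2017,0,
canagliflozin,year,2018,1155,54.3
dapagliflozin,year,2018,30,8.3
empagliflozin,year,2018,57,5.4
ertugliflozin,year,2018,0,
canagliflozin,year,2019,500,23.5
dapagliflozin,year,2019,70,19.4
empagliflozin,year,2019,151,14.4
ertugliflozin,year,2019,0,
canagliflozin,year,2020,165,7.8
dapagliflozin,year,2020,48,13.3
empagliflozin,year,2020,130,12.4
ertugliflozin,year,2020,0,
canagliflozin,year,2021,20,0.9
dapagliflozin,year,2021,44,12.2
empagliflozin,year,2021,158,15.1
ertugliflozin,year,2021,0,
canagliflozin,year,2022,43,2.0
dapagliflozin,year,2022,49,13.6
empagliflozin,year,2022,156,14.9
ertugliflozin,year,2022,2,100.0
canagliflozin,year,2023,61,2.9
dapagliflozin,year,2023,56,15.5
empagliflozin,year,2023,177,16.9
ertugliflozin,year,2023,0,
canagliflozin,year,2024,20,0.9
dapagliflozin,year,2024,47,13.0
empagliflozin,year,2024,197,18.8
ertugliflozin,year,2024,0,
canagliflozin,event,Fournier's gangrene,159,7.5
dapagliflozin,event,Fournier's gangrene,218,60.4
empagliflozin,event,Fournier's gangrene,781,74.5
ertugliflozin,event,Fournier's gangrene,0,
canagliflozin,event,Cellulitis gangrenous,5,0.2
dapagliflozin,event,Cellulitis gangrenous,1,0.28
empagliflozin,event,Cellulitis gangrenous,3,0.3
ertugliflozin,event,Cellulitis gangrenous,0,
canagliflozin,event,Diabetic gangrene,19,0.9
dapagliflozin,event,Diabetic gangrene,2,0.28
empagliflozin,event,Diabetic gangrene,4,0.3
ertugliflozin,event,Diabetic gangrene,0,
canagliflozin,event,Amputation,1907,89.6
dapagliflozin,event,Amputation,119,33
empagliflozin,event,Amputation,211,20.1
ertugliflozin,event,Amputation,2,100
canagliflozin,event,Leg amputation,414,19.4
dapagliflozin,event,Leg amputation,27,7.5
empagliflozin,event,Leg amputation,50,4.8
ertugliflozin,event,Leg amputation,0,
canagliflozin,event,Foot amputation,284,13.3
dapagliflozin,event,Foot amputation,19,5.3
empagliflozin,event,Foot amputation,24,2.3
ertugliflozin,event,Foot amputation,0,
canagliflozin,event,Limb amputation,104,4.9
dapagliflozin,event,Limb amputation,6,1.7
empagliflozin,event,Limb amputation,14,1.3
ertugliflozin,event,Limb amputation,0,
canagliflozin,event,Toe amputation,1071,50.3
dapagliflozin,event,Toe amputation,58,16.1
empagliflozin,event,Toe amputation,104,9.9
ertugliflozin,event,Toe amputation,2,100
canagliflozin,event,Diabetic foot,607,28.5
dapagliflozin,event,Diabetic foot,17,4.7
empagliflozin,event,Diabetic foot,39,3.7
ertugliflozin,event,Diabetic foot,2,100
canagliflozin,event,Dry gangrene,50,2.4
dapagliflozin,event,Dry gangrene,5,1.4
empagliflozin,event,Dry gangrene,5,0.5
ertugliflozin,event,Dry gangrene,2,100
canagliflozin,event,Gas gangrene,52,2.4
dapagliflozin,event,Gas gangrene,0,
empagliflozin,event,Gas gangrene,3,0.3
ertugliflozin,event,Gas gangrene,0,
canagliflozin,event,Osteomyelitis,1125,52.9
dapagliflozin,event,Osteomyelitis,16,4.4
empagliflozin,event,Osteomyelitis,44,4.2
ertugliflozin,event,Osteomyelitis,0,
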