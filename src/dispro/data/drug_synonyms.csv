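synonym,generic
canagliflozin,canagliflozin
invokana,canagliflozin
invokamet,canagliflozin
invokamet,metformin
invokamet xr,canagliflozin
invokamet xr,metformin
canagliflozin/metformin,canagliflozin
canagliflozin/metformin,metformin
empagliflozin,empagliflozin
jardiance,empagliflozin
synjardy,empagliflozin
synjardy,metformin
synjardy xr,empagliflozin
synjardy xr,metformin
glyxambi,empagliflozin
glyxambi,linagliptin
trijardy xr,empagliflozin
trijardy xr,linagliptin
trijardy xr,metformin
empagliflozin/metformin,empagliflozin
empagliflozin/metformin,metformin
empagliflozin/linagliptin,empagliflozin
empagliflozin/linagliptin,linagliptin
dapagliflozin,dapagliflozin
farxiga,dapagliflozin
forxiga,dapagliflozin
edistride,dapagliflozin
xigduo,dapagliflozin
xigduo,metformin
xigduo xr,dapagliflozin
xigduo xr,metformin
qtern,dapagliflozin
qtern,saxagliptin
dapagliflozin/metformin,dapagliflozin
dapagliflozin/metformin,metformin
dapagliflozin/saxagliptin,dapagliflozin
dapagliflozin/saxagliptin,saxagliptin
ertugliflozin,ertugliflozin
steglatro,ertugliflozin
segluromet,ertugliflozin
segluromet,metformin
steglujan,ertugliflozin
steglujan,sitagliptin
ertugliflozin/metformin,ertugliflozin
ertugliflozin/metformin,metformin
ertugliflozin/sitagliptin,ertugliflozin
ertugliflozin/sitagliptin,sitagliptin
ipragliflozin,ipragliflozin
suglat,ipragliflozin
tofogliflozin,tofogliflozin
apleway,tofogliflozin
deberza,tofogliflozin
luseogliflozin,luseogliflozin
lusefi,luseogliflozin
remogliflozin,remogliflozin
remogliflozin etabonate,remogliflozin
metformin,metformin
linagliptin,linagliptin
saxagliptin,saxagliptin
sitagliptin,sitagliptin
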