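country_code,region
US,North America
CA,North America
MX,North America
GT,North America
CU,North America
DO,North America
HN,North America
PA,North America
CR,North America
JM,North America
TT,North America
BS,North America
BZ,North America
SV,North America
NI,North America
HT,North America
GB,Europe
DE,Europe
FR,Europe
IT,Europe
ES,Europe
NL,Europe
BE,Europe
SE,Europe
NO,Europe
DK,Europe
FI,Europe
IE,Europe
PT,Europe
AT,Europe
CH,Europe
PL,Europe
CZ,Europe
SK,Europe
HU,Europe
RO,Europe
BG,Europe
GR,Europe
HR,Europe
SI,Europe
RS,Europe
UA,Europe
RU,Europe
EE,Europe
LV,Europe
LT,Europe
IS,Europe
LU,Europe
MT,Europe
CY,Europe
JP,Asia
CN,Asia
KR,Asia
IN,Asia
TW,Asia
HK,Asia
SG,Asia
TH,Asia
MY,Asia
ID,Asia
PH,Asia
VN,Asia
SA,Asia
AE,Asia
IL,Asia
TR,Asia
IR,Asia
IQ,Asia
PK,Asia
BD,Asia
LK,Asia
KZ,Asia
QA,Asia
KW,Asia
OM,Asia
BH,Asia
JO,Asia
LB,Asia
AU,Oceania
NZ,Oceania
FJ,Oceania
PG,Oceania
BR,South America
AR,South America
CL,South America
CO,South America
PE,South America
VE,South America
EC,South America
UY,South America
PY,South America
BO,South America
ZA,Africa
EG,Africa
NG,Africa
KE,Africa
MA,Africa
TN,Africa
DZ,Africa
GH,Africa
ET,Africa
TZ,Africa
UG,Africa
ZW,Africa
SN,Africa
CM,Africa
CI,Africa
LY,Africa
SD,Africa
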