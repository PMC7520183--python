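scope,location,year,month,total
location_year,BC,2012,,83
location_year,BC,2013,,52
location_year,BI,2016,,108
location_year,CB,2012,,133
location_year,CB,2013,,130
location_year,CB,2014,,138
location_year,CM,2012,,157
location_year,CM,2013,,128
location_year,FR,2012,,124
location_year,FR,2013,,92
month,,,Apr,56
month,,,May,162
month,,,June,135
month,,,July,155
month,,,Aug,142
month,,,Sept,247
month,,,Oct,203
month,,,Nov,45
grand,,,,1145
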