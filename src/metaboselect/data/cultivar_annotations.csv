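cultivar,region,genetic_origin,usage_type,metabolome_group
Saaz,Central Europe,European,Aroma,2
Tettnanger,Central Europe,European,Aroma,2
Hallertau Mittelfruh,Central Europe,North American,Aroma,2
Perle,Central Europe,European,Dual use,2
Nugget,Central Europe,North American,Dual use,1
Styrian Cardinal,Central Europe,North American,Dual use,1
Amarillo,North America,North American,Aroma,2
Fuggle,North America,European,Aroma,2
Willamette,North America,European,Aroma,2
Cashmere,North America,North American,Dual use,1
Mosaic,North America,North American,Dual use,1
Cascade,North America,North American,Aroma,2
Kohatu,Oceania,North American,Aroma,2
Wai-iti,Oceania,European,Aroma,2
Nelson Sauvin,Oceania,North American,Dual use,1
Galaxy,Oceania,North American,Dual use,1
Waimea,Oceania,North American,Dual use,1
Ella,Oceania,North American,Aroma,1
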