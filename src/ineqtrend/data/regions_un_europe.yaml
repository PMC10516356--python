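# United Nations geoscheme subregions of Europe for the countries covered
# by the 2003-2015 school-survey waves.
Denmark: North
Estonia: North
Finland: North
Iceland: North
Latvia: North
Lithuania: North
Norway: North
Sweden: North
Bulgaria: East
Czech Republic: East
Hungary: East
Poland: East
Romania: East
Slovakia: East
Ukraine: East
Croatia: South
Greece: South
Italy: South
Malta: South
Slovenia: South
Belgium: West
France: West
Netherlands: West
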