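# Common MeSH geographic descriptors (Class 4): fallback list used when
# records carry no class metadata.
Africa
Asia
Australia
Austria
Belgium
Brazil
California
Canada
China
Denmark
England
Europe
Finland
France
Germany
Great Britain
Greece
India
Ireland
Israel
Italy
Japan
Korea
London
Mexico
Netherlands
New York
North America
Norway
Poland
Russia
Scotland
South America
Spain
Sweden
Switzerland
Taiwan
Turkey
United Kingdom
United States
Wales
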