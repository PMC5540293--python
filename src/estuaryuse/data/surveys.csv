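year,date,time,tide_type
2003,02-Aug,1245-1430,Spring High
2003,03-Aug,1400-1600,Spring High
2003,04-Aug,1400-1600,Spring High
2003,06-Aug,1645-1845,Neap High
2003,09-Aug,0800-1000,Neap High
2003,12-Aug,1000-1215,Spring High
2003,13-Aug,1030-1245,Spring High
2005,29-Jul,1630-1830,Neap High
2005,30-Jul,1630-1845,Neap High
2005,31-Jul,1715-1930,Neap High
2005,01-Aug,1900-2045,Neap High
2005,03-Aug,0845-1100,Neap High
2005,05-Aug,1000-1215,Spring High
2005,07-Aug,1145-1345,Spring High
2005,10-Aug,1330-1515,Spring High
2005,11-Aug,1415-1615,Spring High
2005,13-Aug,1530-1730,Neap High
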