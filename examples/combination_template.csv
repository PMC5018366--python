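# Combination experiment template.
# First row: doses of drug A (laid out in columns); first column: doses of
# drug B (rows); body: responses in % of untreated control (100 = untreated,
# 0 = complete effect). Each dose series must include the 0 dose (the
# single-agent axes). Top-left cell: blank or "DrugA|DrugB".
# Replicates: save sibling files named <name>_rep1.csv, <name>_rep2.csv, ...
# or use one XLSX workbook with one sheet per replicate.
DrugA|DrugB,0,0.1,0.3,1,3,10
0,100,92,78,52,25,12
0.1,95,88,72,45,20,10
0.3,85,76,60,35,15,8
1,65,55,42,22,10,6
3,40,32,24,12,6,4
10,22,17,12,7,4,3
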