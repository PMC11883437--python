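element	mass	abundance
C	12.0	0.9893
C	13.0033548378	0.0107
H	1.0078250319	0.999885
H	2.0141017780	0.000115
N	14.0030740052	0.996358
N	15.0001088984	0.003642
O	15.9949146221	0.99757
O	16.9991315000	0.00038
O	17.9991604000	0.00205
S	31.9720706900	0.9499
S	32.9714585000	0.0075
S	33.9678668300	0.0425
S	35.9670808800	0.0001
Si	27.9769265327	0.92223
Si	28.9764947200	0.04685
Si	29.9737702200	0.03092
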