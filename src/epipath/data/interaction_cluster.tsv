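snp1	chr1	pos1	snp2	chr2	pos2	p_dosage	p_z
rs10954428	7	1050000	rs10797020	1	2030000	4.24e-8	1.44e-8
rs10954428	7	1050000	rs1578761	1	2000500	2.04e-7	8.66e-8
rs10954428	7	1050000	rs10489833	1	2020000	6.25e-8	2.26e-8
rs10954428	7	1050000	rs11264997	1	2040000	8.54e-8	3.21e-8
rs12540206	7	1100000	rs1578761	1	2000500	4.95e-9	1.21e-9
rs12540206	7	1100000	rs975118	1	2010000	3.43e-9	7.92e-10
rs12540206	7	1100000	rs10489833	1	2020000	1.97e-9	4.19e-10
rs12540206	7	1100000	rs10797020	1	2030000	7.25e-10	1.26e-10
rs12540206	7	1100000	rs11264997	1	2040000	1.70e-9	3.41e-10
rs12540206	7	1100000	rs7512592	1	2050000	1.97e-9	4.19e-10
rs12540206	7	1100000	rs1873511	1	2065000	4.38e-9	1.04e-9
rs12540206	7	1100000	rs6697656	1	2070000	1.13e-8	3.28e-9
rs6963221	7	1150000	rs1578761	1	2000500	9.53e-9	2.67e-9
rs6963221	7	1150000	rs975118	1	2010000	6.81e-9	1.83e-9
rs6963221	7	1150000	rs10489833	1	2020000	3.81e-9	9.33e-10
rs6963221	7	1150000	rs10797020	1	2030000	1.43e-9	2.87e-10
rs6963221	7	1150000	rs11264997	1	2040000	2.40e-9	5.29e-10
rs6963221	7	1150000	rs7512592	1	2050000	3.81e-9	9.33e-10
rs6963221	7	1150000	rs6679056	1	2060000	2.58e-8	8.63e-9
rs6963221	7	1150000	rs1873511	1	2065000	6.21e-9	1.61e-9
rs6963221	7	1150000	rs6697656	1	2070000	2.11e-8	6.83e-9
rs6976491	7	1250000	rs1578761	1	2000500	7.46e-9	2.01e-9
rs6976491	7	1250000	rs975118	1	2010000	5.11e-9	1.31e-9
rs6976491	7	1250000	rs10489833	1	2020000	3.00e-9	7.00e-10
rs6976491	7	1250000	rs10797020	1	2030000	1.13e-9	2.16e-10
rs6976491	7	1250000	rs11264997	1	2040000	1.89e-9	4.01e-10
rs6976491	7	1250000	rs7512592	1	2050000	3.00e-9	7.00e-10
rs6976491	7	1250000	rs6679056	1	2060000	2.09e-8	7.03e-9
rs6976491	7	1250000	rs1873511	1	2065000	4.81e-9	1.20e-9
rs6976491	7	1250000	rs6697656	1	2070000	1.68e-8	5.30e-9
rs7800006	7	1200000	rs1578761	1	2000500	1.31e-9	2.65e-10
rs7800006	7	1200000	rs975118	1	2010000	8.72e-10	1.66e-10
rs7800006	7	1200000	rs10489833	1	2020000	5.26e-10	9.00e-11
rs7800006	7	1200000	rs10797020	1	2030000	1.96e-10	2.63e-11
rs7800006	7	1200000	rs11264997	1	2040000	4.42e-10	7.09e-11
rs7800006	7	1200000	rs7512592	1	2050000	5.26e-10	9.00e-11
rs7800006	7	1200000	rs6679056	1	2060000	6.87e-9	1.98e-9
rs7800006	7	1200000	rs1873511	1	2065000	1.12e-9	2.19e-10
rs7800006	7	1200000	rs6697656	1	2070000	3.10e-9	7.41e-10
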