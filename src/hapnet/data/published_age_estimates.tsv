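label	pattern	years	years_sd	rho	sigma
HAP1	-++-+++	94964.7	18992.9	4.705	0.94
HAP2	+++-+++	107626.6	17937.7	5.333	0.88
HAP3	-----+-	13453.3	1245.4	0.666	0.66
HAP4	-----++	36324	1816.2	1.8	0.9
HAP5	++---++	40360	10090	2	0.5
HAP6	+----++	59946.4	19982.1	2.97	0.99
HAP7	-++++++	80720	13453.3	4	0.66
HAP8	-+--+-+	30270	10090	1.5	0.5
HAP9	++-++++	60540	10090	3	0.5
HAP11	-++--++	40360	10090	2	0.5
HAP12	+-----+	38235.7	19117.8	1.894	0.94
HAP13	------+	16816.6	16816.6	0.833	0.83
HAP14	-+----+	26906.6	13453.3	1.33	0.66
HAP15	-+--+++	73381.8	18345.4	3.63	0.90
HAP16	+----+-	20180	10090	1	0.5
HAP17	-++---+	30270	10090	1.5	0.5
HAP18	+---+++	40360	10090	2	0.5
HAP19	-+-++++	80720	16144	4	0.8
HAP20	-++--+-	80720	16144	4	0.8
HAP21	--+-+++	60540	10090	3	0.5
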