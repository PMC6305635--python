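label	pattern	Turkey	Iran	India	Thailand	Italia	Holland	Belgium	Mexico
HAP1	-++-+++	0.0652	0.0449	0	1	0	0	0	0
HAP2	+++-+++	0.174	0	0	0	0	0	0	0
HAP3	-----+-	0.0435	0	0	0	0	0	0	0
HAP4	-----++	0.0652	0	0.24	0	0	0	0	0
HAP5	++---++	0.0217	0	0	0	0	0	0	0
HAP6	+----++	0.217	0.584	0.76	0	1	1	1	1
HAP7	-++++++	0.0435	0	0	0	0	0	0	0
HAP8	-+--+-+	0.0217	0	0	0	0	0	0	0
HAP9	++-++++	0.0217	0	0	0	0	0	0	0
HAP10	-------	0.0217	0	0	0	0	0	0	0
HAP11	-++--++	0.0217	0	0	0	0	0	0	0
HAP12	+-----+	0.0435	0.18	0	0	0	0	0	0
HAP13	------+	0.109	0	0	0	0	0	0	0
HAP14	-+----+	0.0435	0	0	0	0	0	0	0
HAP15	-+--+++	0.0217	0.101	0	0	0	0	0	0
HAP16	+----+-	0.0217	0	0	0	0	0	0	0
HAP17	-++---+	0.0217	0	0	0	0	0	0	0
HAP18	+---+++	0.0123	0	0	0	0	0	0	0
HAP19	-+-++++	0	0.0449	0	0	0	0	0	0
HAP20	-++--+-	0	0.0449	0	0	0	0	0	0
HAP21	--+-+++	0.0094	0	0	0	0	0	0	0
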