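organ	target	genotype	mouse_id	delta_ct
Liver	Gas2l1	WT	WT1	2.1
Liver	Gas2l1	WT	WT2	5.6
Liver	Gas2l1	WT	WT3	2.7
Liver	Gas2l1	MUT	MUT1	>9.4
Liver	Gas2l1	MUT	MUT2	2.2
Liver	Gas2l1	MUT	MUT3	1.1
Liver	Osbpl2	WT	WT1	6.0
Liver	Osbpl2	WT	WT2	5.5
Liver	Osbpl2	WT	WT3	5.6
Liver	Osbpl2	MUT	MUT1	-1.5
Liver	Osbpl2	MUT	MUT2	0.2
Liver	Osbpl2	MUT	MUT3	0.1
Liver	Ndufs7	WT	WT1	15.6
Liver	Ndufs7	WT	WT2	17.1
Liver	Ndufs7	WT	WT3	15.3
Liver	Ndufs7	MUT	MUT1	>12.4
Liver	Ndufs7	MUT	MUT2	11.8
Liver	Ndufs7	MUT	MUT3	12.0
Liver	Wrap73	WT	WT1	7.2
Liver	Wrap73	WT	WT2	8.9
Liver	Wrap73	WT	WT3	9.1
Liver	Wrap73	MUT	MUT1	-0.2
Liver	Wrap73	MUT	MUT2	1.2
Liver	Wrap73	MUT	MUT3	1.7
Testis	Gas2l1	WT	WT1	1.5
Testis	Gas2l1	WT	WT2	>6.4
Testis	Gas2l1	WT	WT3	>6.1
Testis	Gas2l1	MUT	MUT1	0.9
Testis	Gas2l1	MUT	MUT2	1.5
Testis	Gas2l1	MUT	MUT3	2.1
Testis	Osbpl2	WT	WT1	2.3
Testis	Osbpl2	WT	WT2	5.2
Testis	Osbpl2	WT	WT3	4.3
Testis	Osbpl2	MUT	MUT1	0.6
Testis	Osbpl2	MUT	MUT2	1.6
Testis	Osbpl2	MUT	MUT3	2.6
Testis	Ndufs7	WT	WT1	>13
Testis	Ndufs7	WT	WT2	>16.8
Testis	Ndufs7	WT	WT3	>18.1
Testis	Ndufs7	MUT	MUT1	11.5
Testis	Ndufs7	MUT	MUT2	9.7
Testis	Ndufs7	MUT	MUT3	17.0
Testis	Wrap73	WT	WT1	6.2
Testis	Wrap73	WT	WT2	7.7
Testis	Wrap73	WT	WT3	7.9
Testis	Wrap73	MUT	MUT1	2.9
Testis	Wrap73	MUT	MUT2	3.0
Testis	Wrap73	MUT	MUT3	3.5
Brain	Gas2l1	WT	WT1	6.7
Brain	Gas2l1	WT	WT2	>6.8
Brain	Gas2l1	WT	WT3	>5.5
Brain	Gas2l1	MUT	MUT1	1.1
Brain	Gas2l1	MUT	MUT2	1.2
Brain	Gas2l1	MUT	MUT3	6.7
Brain	Osbpl2	WT	WT1	4.4
Brain	Osbpl2	WT	WT2	7.0
Brain	Osbpl2	WT	WT3	6.5
Brain	Osbpl2	MUT	MUT1	-0.7
Brain	Osbpl2	MUT	MUT2	1.5
Brain	Osbpl2	MUT	MUT3	0.9
Brain	Ndufs7	WT	WT1	>13.8
Brain	Ndufs7	WT	WT2	>18.1
Brain	Ndufs7	WT	WT3	>18.3
Brain	Ndufs7	MUT	MUT1	10.7
Brain	Ndufs7	MUT	MUT2	11.9
Brain	Ndufs7	MUT	MUT3	17.5
Brain	Wrap73	WT	WT1	10.1
Brain	Wrap73	WT	WT2	>13
Brain	Wrap73	WT	WT3	>12.9
Brain	Wrap73	MUT	MUT1	3.6
Brain	Wrap73	MUT	MUT2	3.4
Brain	Wrap73	MUT	MUT3	5.7
Heart	Pick1	WT	WT1	>8.6
Heart	Pick1	WT	WT2	>7.0
Heart	Pick1	WT	WT3	>2.6
Heart	Pick1	MUT	MUT1	5.0
Heart	Pick1	MUT	MUT2	6.2
Heart	Pick1	MUT	MUT3	4.0
Heart	Gas2l1	WT	WT1	3.3
Heart	Gas2l1	WT	WT2	>6.3
Heart	Gas2l1	WT	WT3	>6
Heart	Gas2l1	MUT	MUT1	-1.3
Heart	Gas2l1	MUT	MUT2	1.5
Heart	Gas2l1	MUT	MUT3	2.5
Heart	Osbpl2	WT	WT1	5.2
Heart	Osbpl2	WT	WT2	8.2
Heart	Osbpl2	WT	WT3	>10.6
Heart	Osbpl2	MUT	MUT1	-0.5
Heart	Osbpl2	MUT	MUT2	0.9
Heart	Osbpl2	MUT	MUT3	3.9
Heart	Ndufs7	WT	WT1	15.8
Heart	Ndufs7	WT	WT2	>20.9
Heart	Ndufs7	WT	WT3	>20.3
Heart	Ndufs7	MUT	MUT1	7.5
Heart	Ndufs7	MUT	MUT2	11.2
Heart	Ndufs7	MUT	MUT3	>19.5
Heart	Wrap73	WT	WT1	8.5
Heart	Wrap73	WT	WT2	>7.9
Heart	Wrap73	WT	WT3	>7.7
Heart	Wrap73	MUT	MUT1	3.6
Heart	Wrap73	MUT	MUT2	3.7
Heart	Wrap73	MUT	MUT3	2.3
Lung	Pick1	WT	WT1	>6.4
Lung	Pick1	WT	WT2	>4.1
Lung	Pick1	WT	WT3	>3.8
Lung	Pick1	MUT	MUT1	3.6
Lung	Pick1	MUT	MUT2	5.4
Lung	Pick1	MUT	MUT3	5.0
Lung	Gas2l1	WT	WT1	3.6
Lung	Gas2l1	WT	WT2	>7.1
Lung	Gas2l1	WT	WT3	>6.7
Lung	Gas2l1	MUT	MUT1	-0.9
Lung	Gas2l1	MUT	MUT2	1.0
Lung	Gas2l1	MUT	MUT3	-0.3
Lung	Osbpl2	WT	WT1	4.4
Lung	Osbpl2	WT	WT2	6.3
Lung	Osbpl2	WT	WT3	>3.6
Lung	Osbpl2	MUT	MUT1	-1.0
Lung	Osbpl2	MUT	MUT2	2.3
Lung	Osbpl2	MUT	MUT3	ND
Lung	Ndufs7	WT	WT1	13.8
Lung	Ndufs7	WT	WT2	>17.4
Lung	Ndufs7	WT	WT3	>14.8
Lung	Ndufs7	MUT	MUT1	8.7
Lung	Ndufs7	MUT	MUT2	10.3
Lung	Ndufs7	MUT	MUT3	>10
Lung	Wrap73	WT	WT1	8.1
Lung	Wrap73	WT	WT2	7.3
Lung	Wrap73	WT	WT3	>10.5
Lung	Wrap73	MUT	MUT1	1.9
Lung	Wrap73	MUT	MUT2	2.1
Lung	Wrap73	MUT	MUT3	3.9
Duodenum	Pick1	WT	WT1	>6.0
Duodenum	Pick1	WT	WT2	8.3
Duodenum	Pick1	WT	WT3	ND
Duodenum	Pick1	MUT	MUT1	3.0
Duodenum	Pick1	MUT	MUT2	ND
Duodenum	Pick1	MUT	MUT3	1.1
Duodenum	Gas2l1	WT	WT1	6.2
Duodenum	Gas2l1	WT	WT2	5.6
Duodenum	Gas2l1	WT	WT3	>3.9
Duodenum	Gas2l1	MUT	MUT1	7.0
Duodenum	Gas2l1	MUT	MUT2	-0.4
Duodenum	Gas2l1	MUT	MUT3	1.7
Duodenum	Osbpl2	WT	WT1	2
Duodenum	Osbpl2	WT	WT2	4.4
Duodenum	Osbpl2	WT	WT3	2.0
Duodenum	Osbpl2	MUT	MUT1	-1.1
Duodenum	Osbpl2	MUT	MUT2	-1.2
Duodenum	Osbpl2	MUT	MUT3	-0.6
Duodenum	Ndufs7	WT	WT1	>11.8
Duodenum	Ndufs7	WT	WT2	>18.6
Duodenum	Ndufs7	WT	WT3	>16.2
Duodenum	Ndufs7	MUT	MUT1	>9.7
Duodenum	Ndufs7	MUT	MUT2	9.1
Duodenum	Ndufs7	MUT	MUT3	11.3
Duodenum	Wrap73	WT	WT1	8.2
Duodenum	Wrap73	WT	WT2	6.4
Duodenum	Wrap73	WT	WT3	>10.0
Duodenum	Wrap73	MUT	MUT1	4.0
Duodenum	Wrap73	MUT	MUT2	1.5
Duodenum	Wrap73	MUT	MUT3	1.1
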