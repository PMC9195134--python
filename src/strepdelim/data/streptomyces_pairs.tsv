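species_a	species_b	anim	mlsa	ddh
S. flavovariabilis NRRL B-16367T	S. variegatus NRRL B-16380T	99.99	0.000	99.8
S. almquistii NRRL B-1685T	S. albus NRRL B-1811T	99.95	0.000	99.7
S. phaeogriseichromatogenes DSM 40710T	S. griseofuscus NRRL B-5429T	99.48	0.001	95.3
S. asterosporus DSM 41452T	S. aureorectus DSM 41692T	99.19	0.002	92.8
S. aureorectus DSM 41692T	S. calvus CECT 3271T	99.20	0.002	92.8
S. asterosporus DSM 41452T	S. calvus CECT 3271T	99.16	0.001	92.9
S. plicatus JCM 4504T	S. vinaceusdrappus JCM 4529T	99.23	0.002	93.6
S. plicatus JCM 4504T	S. geysiriensis JCM 4962T	98.97	0.001	91.2
S. geysiriensis JCM 4962T	S. vinaceusdrappus JCM 4529T	99.01	0.002	91.4
S. hygroscopicus subsp. hygroscopicus NBRC 13472T	S. endus NBRC 12859T	98.94	0.000	90.1
S. puniceus NRRL ISP-5083T	S. floridae NRRL 2423T	98.83	0.002	89.8
S. sporoclivatus NBRC 100767T	S. antimycoticus NBRC 12839T	98.75	0.003	88.6
S. puniceus NRRL ISP-5083T	S. californicus NRRL B-2098T	98.63	0.001	87.6
S. californicus NRRL B-2098T	S. floridae NRRL 2423T	98.62	0.002	87.5
S. griseorubens JCM 4383T	S. matensis JCM 4277T	97.95	0.008	80.9
S. galilaeus ATCC 14969T	S. bobili NRRL B-1338T	97.74	0.004	79.6
S. glebosus NBRC 13786T	S. platensis DSM 40041T	97.78	0.008	79.4
S. castelarensis NRRL B-24289T	S. sporoclivatus NBRC 100767T	97.49	0.006	76.2
S. castelarensis NRRL B-24289T	S. antimycoticus NBRC 12839T	97.47	0.005	75.8
S. olivaceoviridis JCM 4499T	S. canarius JCM 4733T	97.41	0.009	76.0
S. griseofuscus NRRL B-5429T	S. murinus NRRL B-2286T	97.15	0.004	74.5
S. phaeogriseichromatogenes DSM 40710T	S. murinus NRRL B-2286T	97.14	0.006	74.7
S. costaricanus DSM 41827T	S. murinus NRRL B-2286T	97.08	0.005	73.9
S. filipinensis JCM 4369T	S. durhamensis NRRL B-3309T	96.97	0.010	72.9
S. melanosporofaciens DSM 40318T	S. sporoclivatus NBRC 100767T	96.91	0.012	72.2
S. antimycoticus NBRC 12839T	S. melanosporofaciens DSM 40318T	96.90	0.010	72.0
S. olivaceoviridis JCM 4499T	S. corchorusii DSM 40340T	96.88	0.006	71.4
S. recifensis NRRL B-3811T	S. griseoluteus JCM 4765T	96.86	0.005	72.4
S. stelliscabiei DSM 41803T	S. bottropensis ATCC 25435T	96.86	0.011	70.9
S. costaricanus DSM 41827T	S. griseofuscus NRRL B-5429T	96.74	0.004	70.9
S. costaricanus DSM 41827T	S. phaeogriseichromatogenes DSM 40710T	96.73	0.003	70.9
S. canarius JCM 4733T	S. corchorusii DSM 40340T	96.69	0.007	69.5
S. castelarensis NRRL B-24289T	S. melanosporofaciens DSM 40318T	96.57	0.009	68.7
S. chartreusis ATCC 14922T	S. osmaniensis OU-63T	96.40	0.008	68.8
S. mirabilis JCM 4551T	S. olivochromogenes DSM 40451T	96.23	0.011	67.0
S. albidoflavus NRRL B-1271T	S. koyangensis VK-A60T	95.90	0.009	64.7
S. longwoodensis DSM 41677T	S. lasalocidi X-537T	95.47	0.008	61.8
S. bauhiniae Bv016T	S. griseoluteus JCM 4765T	95.27	0.014	60.6
S. rhizosphaericola 1AS2cT	S. cavourensis DSM 41795T	95.21	0.012	59.8
S. recifensis NRRL B-3811T	S. bauhiniae Bv016T	95.21	0.015	60.7
S. xiaopingdaonensis L180T	S. sulphureus DSM 40104T	95.20	0.019	59.7
S. bauhiniae Bv016T	S. seoulensis KCTC 9819T	95.18	0.013	60.2
S. aquilus GGCR-6T	S. antibioticus DSM 40234T	94.86	0.017	58.4
S. achromogenes subsp. achromogenes NRRL B-2120T	S. achromogenes subsp. rubradiris JCM 4955T	94.75	0.016	56.2
S. parvus NRRL B-1455T	S. mediolani NRRL WC-3934T	94.53	0.029	56.1
S. recifensis NRRL B-3811T	S. seoulensis KCTC 9819T	94.47	0.019	56.6
S. galbus JCM 4639T	S. lasalocidi X-537T	94.44	0.009	55.4
S. seoulensis KCTC 9819T	S. griseoluteus JCM 4765T	94.39	0.019	55.8
S. longwoodensis DSM 41677T	S. galbus JCM 4639T	94.33	0.010	55.0
S. ochraceiscleroticus NRRL ISP-5594T	S. violens NRRL ISP-5597T	94.24	0.014	54.5
S. reniochalinae LHW50302T	S. diacarni LHW51701T	93.51	0.018	50.2
S. phaeoluteigriseus DSM 41896T	S. bobili NRRL B-1338T	93.47	0.021	50.7
S. violaceusniger NBRC 13459T	S. antioxidans MUSC 164T	93.34	0.027	48.1
S. sedi JCM 16909T	S. zhaozhouensis CGMCC 4.7095T	93.21	0.021	48.7
S. qaidamensis S10T	S. variegatus NRRL B-16380T	93.10	0.037	49.0
S. tirandamycinicus HNM0039T	S. spongiicola HNM0071T	92.95	0.020	45.1
S. flavovariabilis NRRL B-16367T	S. iakyrus NRRL ISP-5482T	92.86	0.033	47.9
S. violaceorubidus NRRL B-16381T	S. rubrogriseus NBRC 15455T	92.80	0.019	47.3
S. hawaiiensis ATCC 12236T	S. tuirus JCM 4255T	92.75	0.031	47.6
S. platensis DSM 40041T	S. libani subsp. libani NBRC 13452T	92.58	0.033	45.9
S. glebosus NBRC 13786T	S. libani subsp. libani NBRC 13452T	92.55	0.033	45.9
S. coelicoflavus NBRC 15399T	S. rubrogriseus NBRC 15455T	92.48	0.018	45.7
S. diastaticus subsp. ardesiacus NBRC 15402T	S. coelicoflavus NBRC 15399T	92.34	0.023	45.4
S. libani subsp. libani NBRC 13452T	S. tubercidicus NBRC 13090T	92.25	0.041	44.6
S. violaceusniger NBRC 13459T	S. sporoclivatus NBRC 100767T	92.09	0.033	43.5
S. violaceusniger NBRC 13459T	S. melanosporofaciens DSM 40318T	92.08	0.033	43.4
S. coelicoflavus NBRC 15399T	S. violaceorubidus NRRL B-16381T	92.02	0.021	43.9
S. decoyicus NRRL 2666T	S. caniferus NBRC 15389T	91.57	0.042	41.6
S. hygroscopicus subsp. hygroscopicus NBRC 13472T	S. melanosporofaciens DSM 40318T	91.40	0.041	42.8
S. tsukubensis NRRL 18488T	S. qinzhouensis SSL-25T	91.30	0.035	39.8
S. tirandamycinicus HNM0039T	S. wuyuanensis CGMCC 4.7042T	91.12	0.033	39.7
S. angustmyceticus NBRC 3934T	S. decoyicus NRRL 2666T	90.89	0.042	39.4
S. decoyicus NRRL 2666T	S. libani subsp. libani NBRC 13452T	90.71	0.026	38.7
S. albidochromogenes DSM 41800T	S. flavidovirens DSM 40150T	90.52	0.050	38.8
S. wuyuanensis CGMCC 4.7042T	S. spongiicola HNM0071T	90.42	0.040	38.0
S. durhamensis NRRL B-3309T	S. fodineus TW1S1T	90.33	0.037	38.1
S. platensis DSM 40041T	S. decoyicus NRRL 2666T	90.20	0.039	37.0
S. hyaluromycini NBRC 110483T	S. humi MUSC 119T	90.15	0.042	37.3
S. platensis DSM 40041T	S. caniferus NBRC 15389T	90.08	0.049	36.5
S. decoyicus NRRL 2666T	S. inhibens NEAU-D10T	90.00	0.050	36.6
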