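row_number,colony_id,name,lat_dm,lon_dm,region,printed_r,printed_lambda,ci_low,ci_high,significant
1,BSA,Bahía San Antonio,40°47'S,64°47'W,Río Negro,-0.0101,0.99,0.74,1.35,0
2,ILP,Islote La Pastosa,41°25'S,65°02'W,Río Negro,0.0159,1.02,0.96,1.08,0
3,IR,Islote Redondo,41°26'S,65°01'W,Río Negro,0.1970,1.22,1.13,1.31,1
4,IP,Isla de los Pájaros,41°27'S,65°02'W,Río Negro,-0.0896,0.91,0.79,1.06,0
5,PP,Punta Pozos,41°34'S,65°01'W,Río Negro,-0.3164,0.73,,,0
6,IN,Islote Notable,42°25'S,64°31'W,Chubut,0.1768,1.19,1.10,1.29,1
7,ESL,Estancia San Lorenzo,42°05'S,63°51'W,Chubut,0.1989,1.22,1.16,1.28,1
8,AO,Asentamiento Oeste,42°06'S,63°56'W,Chubut,0.0441,1.05,1.01,1.09,1
9,CE,Caleta Externa,42°16'S,63°38'W,Chubut,0.0916,1.10,1.07,1.13,1
10,I1°,Isla Primera,42°21'S,63°37'W,Chubut,0.0451,1.05,1.02,1.07,1
11,I2°,Isla Segunda,42°20'S,63°39'W,Chubut,0.1474,1.16,1.16,1.20,1
12,CI,Caleta Interna,42°27'S,63°36'W,Chubut,-0.0179,0.98,0.96,1.01,0
13,EP,El Pedral,42°57'S,64°23'W,Chubut,0.5622,1.76,1.42,2.11,1
14,PC,Punta Clara,43°58'S,65°15'W,Chubut,-0.0188,0.98,,,0
15,PT,Punta Tombo,44°02'S,65°11'W,Chubut,-0.0167,0.98,0.98,0.99,1
16,PL,Punta Lobería,44°35'S,65°22'W,Chubut,0.0445,1.05,,,0
17,IBM,Isla Blanca Mayor,44°46'S,65°38'W,Chubut,-0.0403,0.96,,,0
18,CDB,Cabo Dos Bahías,44°54'S,65°32'W,Chubut,-0.0030,1.00,0.99,1.01,0
19,IA,Isla Arce,45°00'S,65°29'W,Chubut,-0.0820,0.92,,,0
20,IL,Isla Leones,45°03'S,65°36'W,Chubut,-0.0675,0.94,0.92,0.95,1
21,Pla,Península Lanaud,45°03'S,65°35'W,Chubut,-0.0044,1.00,,,0
22,IB,Isla Buque,45°03'S,65°37'W,Chubut,-0.0236,0.98,,,0
23,ISO,Isla Sudoeste,45°03'S,65°36'W,Chubut,-0.0778,0.93,,,0
24,IT,Isla Tova,45°06'S,66°00'W,Chubut,-0.0231,0.98,,,0
25,ITa,Isla Tovita,45°07'S,65°57'W,Chubut,-0.0631,0.94,0.92,0.96,1
26,IE,Isla Este,45°07'S,65°56'W,Chubut,0.1279,1.14,,,0
27,IG,Isla Gaviota,45°06'S,65°58'W,Chubut,-0.0498,0.95,0.951,0.952,1
28,IVN1,Isla Vernaci Norte,45°11'S,66°30'W,Chubut,0.0058,1.01,0.99,1.03,0
29,IVN2,Isla Vernaci Norte2,45°11'S,66°30'W,Chubut,0.0112,1.01,1.00,1.02,0
30,IVE,Isla Vernaci Este,45°11'S,66°29'W,Chubut,-0.0216,0.98,0.96,1.00,0
31,IVNO,Isla Vernaci Noroeste,45°10'S,66°31'W,Chubut,0.1136,1.12,1.03,1.21,1
32,IVSO,Isla Vernaci Sudoeste,45°11'S,66°31'W,Chubut,-0.0195,0.98,0.96,1.00,0
33,IVF1,Isla Vernaci Fondo1,45°11'S,66°30'W,Chubut,-0.0022,1.00,,,0
34,PPaj,Punta Pájaros,46°57'S,66°51'W,Santa Cruz,0.0394,1.04,,,0
35,ICh,Isla Chaffers,47°46'S,65°52'W,Santa Cruz,0.0009,1.00,0.99,1.01,0
36,IPa,Isla Pájaros,47°45'S,65°58'W,Santa Cruz,0.0197,1.02,1.01,1.03,1
37,IQ,Isla Quiroga,47°45'S,65°56'W,Santa Cruz,0.0334,1.03,1.03,1.04,1
38,ILg,Isla Larga,47°45'S,65°56'W,Santa Cruz,0.0896,1.09,,,0
39,ICP,Islote Cañadon del Puerto,47°45'S,66°00'W,Santa Cruz,-0.0109,0.99,,,0
40,IdR,Isla del Rey,47°46'S,66°03'W,Santa Cruz,-0.0138,0.99,,,0
41,IBti,Islote Burlotti,47°46'S,65°57'W,Santa Cruz,0.0098,1.01,,,0
42,IPno,Isla Pingüino,47°54'S,65°43'W,Santa Cruz,-0.0177,0.98,,,0
43,ICta,Isla Chata,47°56'S,65°44'W,Santa Cruz,0.0312,1.03,,,0
44,ISch,Isla Schwarz,48°04'S,65°54'W,Santa Cruz,-0.0053,0.99,,,0
45,IteB,Islote Burgos,48°05'S,65°54'W,Santa Cruz,-0.0235,0.98,,,0
46,ILi,Isla Liebres,48°06'S,65°54'W,Santa Cruz,-0.0277,0.97,,,0
47,PM,Punta Medanosa,48°06'S,65°55'W,Santa Cruz,-0.0519,0.95,,,0
48,PS,Punta Sur,48°07'S,65°56'W,Santa Cruz,0.0253,1.03,,,0
49,E8J,Estancia 8 de Julio,48°07'S,66°08'W,Santa Cruz,0.0490,1.05,1.04,1.06,1
50,IRC,Isla Rasa Chica,48°22'S,66°20'W,Santa Cruz,-0.0466,0.95,,,0
51,Iba,Islote del Bajío,48°21'S,66°21'W,Santa Cruz,0.1149,1.12,,,0
52,IsN,Islote sin Nombre,48°22'S,66°21'W,Santa Cruz,-0.0224,0.98,,,0
53,CG,Cabo Guardián,48°21'S,66°21'W,Santa Cruz,0.0142,1.01,1.01,1.02,1
54,BC,Banco Cormorán,49°16'S,67°40'W,Santa Cruz,0.0081,1.01,0.99,1.02,0
55,BJ,Banco Justicia,49°17'S,67°41'W,Santa Cruz,-0.0433,0.96,,,0
56,IL(SC),Isla Leones (Sta Cruz),50°04'S,68°26'W,Santa Cruz,0.0053,1.01,,,0
57,PE,Punta Entrada,50°08'S,68°22'W,Santa Cruz,-0.0128,0.99,,,0
58,ML,Monte León,50°22'S,68°53'W,Santa Cruz,0.0137,1.01,1.01,1.02,1
59,ID,Isla Deseada,51°34'S,69°02'W,Santa Cruz,0.0036,1.00,0.97,1.03,0
60,CV,Cabo Vírgenes,52°22'S,68°24'W,Santa Cruz,0.0132,1.01,1.01,1.02,1
61,IMar,Isla Martillo,54°54'S,67°22'W,Tierra del Fuego,0.0624,1.06,1.04,1.09,1
62,BF,Bahía Franklin,54°52'S,64°42'W,Tierra del Fuego,0.1076,1.11,,,0
63,IGo,Isla Gofré,54°42'S,64°14'W,Tierra del Fuego,-0.0634,0.94,,,0
64,SJS,San Juan de Salvamento,54°43'S,63°48'W,Tierra del Fuego,0.0733,1.08,,,0
65,IM,Islas Malvinas,51°47'S,59°31'W,Malvinas,-0.0855,0.92,,,0
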