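district,village,latitude,longitude,altitude,agroecology
Abergelle,Adi_Weyane,13.55,38.94,1699,Midland
Abergelle,Lemlem,13.28,39.06,1598,Lowland
Hawzien,Debrebzien,14.16,39.39,2187,Midland
Hawzien,Debrehiwot,13.96,39.38,2106,Midland
Ofla,Selam-Bkalsi,12.65,39.38,2809,Highland
Raya_Azebo,Genete,12.76,39.68,1671,Midland
Raya_Azebo,Rabia-Tsigea,12.84,39.63,1924,Midland
Hintalo_wajirat,Mesano,13.24,39.44,2033,Midland
Hintalo_wajirat,Meseret,13.75,39.72,2158,Midland
Tahtay-Adyabo,Gemhalo,14.57,37.76,1062,Lowland
Tahtay-Adyabo,May-Kuhli,14.23,37.73,1111,Lowland
Tahtay-Qoraro,Adi_Gidad,14.09,38.26,1888,Midland
Tahtay-Qoraro,May-Tafat,14.23,38.34,1895,Midland
Kafta_Humera,May-Kadra,14.07,36.56,626,Lowland
Kafta_Humera,Adi-Goshu,14.15,37.35,1158,Lowland
Kafta_Humera,Adebay,14.20,36.75,665,Lowland
Welkayt,Mogue,14.05,37.49,907,Lowland
Welkayt,Adi_Remets,13.77,37.33,1970,Midland
Tselemti,May_Dagusha,13.68,38.68,1245,Lowland
Tselemti,Dima,13.68,38.32,1613,Lowland
Tsegedie,Enda_mariam,13.39,37.41,2850,Highland
Tsegedie,Enda_Slassie,13.42,37.39,2584,Highland
Ahferom,Sefo,14.36,39.25,2175,Highland
Ahferom,May_Keyah,14.42,39.4,2419,Highland
Adwa,Mariam_Shewito,14.23,39.05,2227,Highland
Adwa,Bete_Yohannes,14.24,38.92,2145,Highland
Laelay_Maichew,Dura,14.2,38.75,1943,Midland
Laelay_Maichew,Madego,14.26,38.71,1662,Lowland
Tahtay_Maichew,Chila,14.3,38.62,1570,Lowland
Tahtay_Maichew,Shenako,13.83,38.64,2064,Midland
Degua_Tembien,Melfa,13.64,39.13,2495,Highland
Degua_Tembien,Seret,13.6,39.17,2494,Highland
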