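drug,total_items,mean_annual_printed,pct_female,top_month,total_2016,total_2019,total_2023,top_bands_female,top_bands_male
Amoxicillin,53415335,6676917,58,12,8130012,6673263,7311226,"0–1,2–5,86+","0–1,2–5,86+"
Nitrofurantoin,27953870,3494234,83,10,2358297,3740424,3808622,"76–80,81–85,86+","76–80,81–85,86+"
Flucloxacillin sodium,26940364,3367546,55,7,3488057,3270904,3384802,"76–80,81–85,86+","76–80,81–85,86+"
Doxycycline hyclate,22868632,2858579,60,12,2415657,2772514,3804564,"76–80,81–85,86+","76–80,81–85,86+"
Penicillin V,15557160,1944645,59,12,1892172,1841679,2447555,"2–5,6–10,16–20","0–1,2–5,6–10"
Trimethoprim,14439590,1804949,75,1,3087875,1488922,1428569,"76–80,81–85,86+","76–80,81–85,86+"
Clarithromycin,14417677,1802210,63,1,2077261,1845315,1743846,"76–80,81–85,86+","76–80,81–85,86+"
Co-amoxiclav,9181476,1147684,60,1,1304696,1094885,1092620,"76–80,81–85,86+","76–80,81–85,86+"
Lymecycline,7938074,992259,58,3,1054631,1032182,861423,"11–15,16–20,21–25","11–15,16–20,21–25"
Cefalexin,5910292,738786,80,12,748696,668339,816579,"76–80,81–85,86+","76–80,81–85,86+"
Azithromycin,5877890,734736,57,12,612414,748885,805700,"71–75,76–80,81–85","76–80,81–85,86+"
Metronidazole,4156192,519524,78,3,599382,520332,474629,"21–25,26–30,31–35","76–80,81–85,86+"
Ciprofloxacin,3564433,445554,48,1,532816,445243,355804,"76–80,81–85,86+","76–80,81–85,86+"
Erythromycin,3397046,424631,66,1,709522,394861,286163,"76–80,81–85,86+","76–80,81–85,86+"
Oxytetracycline,2432724,304090,51,3,463514,310851,178452,"61–65,66–70,76–80","71–75,76–80,81–85"
Pivmecillinam hydrochloride,1790378,223797,79,10,108361,223030,301447,"76–80,81–85,86+","76–80,81–85,86+"
Erythromycin ethylsuccinate,1576325,197041,50,12,341227,171870,164552,"0–1,2–5,6–10","0–1,2–5,6–10"
Co-trimoxazole,1417031,177129,44,12,129051,173722,228051,"66–70,76–80,81–85","76–80,81–85,86+"
Methenamine hippurate,1060060,132508,80,12,40789,82081,319013,"76–80,81–85,86+","76–80,81–85,86+"
Rifaximin,593273,74159,41,12,33589,71036,109205,"56–60,61–65,66–70","56–60,61–65,66–70"
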