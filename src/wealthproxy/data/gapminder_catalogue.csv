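category,picture_id,monthly_income_usd
house,house_00,50.0
house,house_01,58.605114876674016
house,house_02,68.69118979416314
house,house_03,80.51310137804697
house,house_04,94.36959110675485
house,house_05,110.61081455352246
house,house_06,129.64718987023335
house,house_07,151.95976911565987
house,house_08,178.1123945131221
house,house_09,208.76594682802008
house,house_10,244.69504592387472
house,house_11,286.8076255224339
house,house_12,336.1678768249668
house,house_13,394.02314078349565
house,house_14,461.8354285936931
house,house_15,541.3183669370273
house,house_16,634.4805015839611
house,house_17,743.6760536467556
house,house_18,871.664411099994
house,house_19,1021.6798589284709
house,house_20,1197.513309993743
house,house_21,1403.6081019705887
house,house_22,1645.1722811563338
house,house_23,1928.3102105817359
house,house_24,2260.1768281801214
house,house_25,2649.1584531418534
house,house_26,3105.084709457808
house,house_27,3639.476921991575
house,house_28,4265.839262086405
house,house_29,5000.0
kitchen,kitchen_00,50.0
kitchen,kitchen_01,58.605114876674016
kitchen,kitchen_02,68.69118979416314
kitchen,kitchen_03,80.51310137804697
kitchen,kitchen_04,94.36959110675485
kitchen,kitchen_05,110.61081455352246
kitchen,kitchen_06,129.64718987023335
kitchen,kitchen_07,151.95976911565987
kitchen,kitchen_08,178.1123945131221
kitchen,kitchen_09,208.76594682802008
kitchen,kitchen_10,244.69504592387472
kitchen,kitchen_11,286.8076255224339
kitchen,kitchen_12,336.1678768249668
kitchen,kitchen_13,394.02314078349565
kitchen,kitchen_14,461.8354285936931
kitchen,kitchen_15,541.3183669370273
kitchen,kitchen_16,634.4805015839611
kitchen,kitchen_17,743.6760536467556
kitchen,kitchen_18,871.664411099994
kitchen,kitchen_19,1021.6798589284709
kitchen,kitchen_20,1197.513309993743
kitchen,kitchen_21,1403.6081019705887
kitchen,kitchen_22,1645.1722811563338
kitchen,kitchen_23,1928.3102105817359
kitchen,kitchen_24,2260.1768281801214
kitchen,kitchen_25,2649.1584531418534
kitchen,kitchen_26,3105.084709457808
kitchen,kitchen_27,3639.476921991575
kitchen,kitchen_28,4265.839262086405
kitchen,kitchen_29,5000.0
floor,floor_00,50.0
floor,floor_01,58.605114876674016
floor,floor_02,68.69118979416314
floor,floor_03,80.51310137804697
floor,floor_04,94.36959110675485
floor,floor_05,110.61081455352246
floor,floor_06,129.64718987023335
floor,floor_07,151.95976911565987
floor,floor_08,178.1123945131221
floor,floor_09,208.76594682802008
floor,floor_10,244.69504592387472
floor,floor_11,286.8076255224339
floor,floor_12,336.1678768249668
floor,floor_13,394.02314078349565
floor,floor_14,461.8354285936931
floor,floor_15,541.3183669370273
floor,floor_16,634.4805015839611
floor,floor_17,743.6760536467556
floor,floor_18,871.664411099994
floor,floor_19,1021.6798589284709
floor,floor_20,1197.513309993743
floor,floor_21,1403.6081019705887
floor,floor_22,1645.1722811563338
floor,floor_23,1928.3102105817359
floor,floor_24,2260.1768281801214
floor,floor_25,2649.1584531418534
floor,floor_26,3105.084709457808
floor,floor_27,3639.476921991575
floor,floor_28,4265.839262086405
floor,floor_29,5000.0
toilet,toilet_00,50.0
toilet,toilet_01,58.605114876674016
toilet,toilet_02,68.69118979416314
toilet,toilet_03,80.51310137804697
toilet,toilet_04,94.36959110675485
toilet,toilet_05,110.61081455352246
toilet,toilet_06,129.64718987023335
toilet,toilet_07,151.95976911565987
toilet,toilet_08,178.1123945131221
toilet,toilet_09,208.76594682802008
toilet,toilet_10,244.69504592387472
toilet,toilet_11,286.8076255224339
toilet,toilet_12,336.1678768249668
toilet,toilet_13,394.02314078349565
toilet,toilet_14,461.8354285936931
toilet,toilet_15,541.3183669370273
toilet,toilet_16,634.4805015839611
toilet,toilet_17,743.6760536467556
toilet,toilet_18,871.664411099994
toilet,toilet_19,1021.6798589284709
toilet,toilet_20,1197.513309993743
toilet,toilet_21,1403.6081019705887
toilet,toilet_22,1645.1722811563338
toilet,toilet_23,1928.3102105817359
toilet,toilet_24,2260.1768281801214
toilet,toilet_25,2649.1584531418534
toilet,toilet_26,3105.084709457808
toilet,toilet_27,3639.476921991575
toilet,toilet_28,4265.839262086405
toilet,toilet_29,5000.0
bed,bed_00,50.0
bed,bed_01,58.605114876674016
bed,bed_02,68.69118979416314
bed,bed_03,80.51310137804697
bed,bed_04,94.36959110675485
bed,bed_05,110.61081455352246
bed,bed_06,129.64718987023335
bed,bed_07,151.95976911565987
bed,bed_08,178.1123945131221
bed,bed_09,208.76594682802008
bed,bed_10,244.69504592387472
bed,bed_11,286.8076255224339
bed,bed_12,336.1678768249668
bed,bed_13,394.02314078349565
bed,bed_14,461.8354285936931
bed,bed_15,541.3183669370273
bed,bed_16,634.4805015839611
bed,bed_17,743.6760536467556
bed,bed_18,871.664411099994
bed,bed_19,1021.6798589284709
bed,bed_20,1197.513309993743
bed,bed_21,1403.6081019705887
bed,bed_22,1645.1722811563338
bed,bed_23,1928.3102105817359
bed,bed_24,2260.1768281801214
bed,bed_25,2649.1584531418534
bed,bed_26,3105.084709457808
bed,bed_27,3639.476921991575
bed,bed_28,4265.839262086405
bed,bed_29,5000.0
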