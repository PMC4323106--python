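# WAG amino acid substitution model (Whelan & Goldman 2001).
# Symmetric exchangeabilities (20x20) then equilibrium frequencies.
A R N D C Q E G H I L K M F P S T W Y V
0.000000 0.551571 0.509848 0.738998 1.027040 0.908598 1.582850 1.416720 0.316954 0.193335 0.397915 0.906265 0.893496 0.210494 1.438550 3.370790 2.121110 0.113133 0.240735 2.006010
0.551571 0.000000 0.635346 0.147304 0.528191 3.035500 0.439157 0.584665 2.137150 0.186979 0.497671 5.351420 0.683162 0.102711 0.679489 1.224190 0.554413 1.163920 0.381533 0.251849
0.5098480 0.6353460 0.0000000 5.4294200 0.2652560 1.5436400 0.9471980 1.1255600 3.9562900 0.5542360 0.1315280 3.0120100 0.1982210 0.0961621 0.1950810 3.9742300 2.0300600 0.0719167 1.0860000 0.1962460
0.7389980 0.1473040 5.4294200 0.0000000 0.0302949 0.6167830 6.1741600 0.8655840 0.9306760 0.0394370 0.0848047 0.4798550 0.1037540 0.0467304 0.4239840 1.0717600 0.3748660 0.1297670 0.3257110 0.1523350
1.0270400 0.5281910 0.2652560 0.0302949 0.0000000 0.0988179 0.0213520 0.3066740 0.2489720 0.1701350 0.3842870 0.0740339 0.3904820 0.3980200 0.1094040 1.4076600 0.5129840 0.7170700 0.5438330 1.0021400
0.9085980 3.0355000 1.5436400 0.6167830 0.0988179 0.0000000 5.4694700 0.3300520 4.2941100 0.1139170 0.8694890 3.8949000 1.5452600 0.0999208 0.9333720 1.0288700 0.8579280 0.2157370 0.2277100 0.3012810
1.5828500 0.4391570 0.9471980 6.1741600 0.0213520 5.4694700 0.0000000 0.5677170 0.5700250 0.1273950 0.1542630 2.5844300 0.3151240 0.0811339 0.6823550 0.7049390 0.8227650 0.1565570 0.1963030 0.5887310
1.4167200 0.5846650 1.1255600 0.8655840 0.3066740 0.3300520 0.5677170 0.0000000 0.2494100 0.0304501 0.0613037 0.3735580 0.1741000 0.0499310 0.2435700 1.3418200 0.2258330 0.3369830 0.1036040 0.1872470
0.316954 2.137150 3.956290 0.930676 0.248972 4.294110 0.570025 0.249410 0.000000 0.138190 0.499462 0.890432 0.404141 0.679371 0.696198 0.740169 0.473307 0.262569 3.873440 0.118358
0.1933350 0.1869790 0.5542360 0.0394370 0.1701350 0.1139170 0.1273950 0.0304501 0.1381900 0.0000000 3.1709700 0.3238320 4.2574600 1.0594700 0.0999288 0.3194400 1.4581600 0.2124830 0.4201700 7.8213000
0.3979150 0.4976710 0.1315280 0.0848047 0.3842870 0.8694890 0.1542630 0.0613037 0.4994620 3.1709700 0.0000000 0.2575550 4.8540200 2.1151700 0.4158440 0.3447390 0.3266220 0.6653090 0.3986180 1.8003400
0.9062650 5.3514200 3.0120100 0.4798550 0.0740339 3.8949000 2.5844300 0.3735580 0.8904320 0.3238320 0.2575550 0.0000000 0.9342760 0.0888360 0.5568960 0.9671300 1.3869800 0.1375050 0.1332640 0.3054340
0.893496 0.683162 0.198221 0.103754 0.390482 1.545260 0.315124 0.174100 0.404141 4.257460 4.854020 0.934276 0.000000 1.190630 0.171329 0.493905 1.516120 0.515706 0.428437 2.058450
0.2104940 0.1027110 0.0961621 0.0467304 0.3980200 0.0999208 0.0811339 0.0499310 0.6793710 1.0594700 2.1151700 0.0888360 1.1906300 0.0000000 0.1614440 0.5459310 0.1719030 1.5296400 6.4542800 0.6498920
1.4385500 0.6794890 0.1950810 0.4239840 0.1094040 0.9333720 0.6823550 0.2435700 0.6961980 0.0999288 0.4158440 0.5568960 0.1713290 0.1614440 0.0000000 1.6132800 0.7953840 0.1394050 0.2160460 0.3148870
3.370790 1.224190 3.974230 1.071760 1.407660 1.028870 0.704939 1.341820 0.740169 0.319440 0.344739 0.967130 0.493905 0.545931 1.613280 0.000000 4.378020 0.523742 0.786993 0.232739
2.121110 0.554413 2.030060 0.374866 0.512984 0.857928 0.822765 0.225833 0.473307 1.458160 0.326622 1.386980 1.516120 0.171903 0.795384 4.378020 0.000000 0.110864 0.291148 1.388230
0.1131330 1.1639200 0.0719167 0.1297670 0.7170700 0.2157370 0.1565570 0.3369830 0.2625690 0.2124830 0.6653090 0.1375050 0.5157060 1.5296400 0.1394050 0.5237420 0.1108640 0.0000000 2.4853900 0.3653690
0.240735 0.381533 1.086000 0.325711 0.543833 0.227710 0.196303 0.103604 3.873440 0.420170 0.398618 0.133264 0.428437 6.454280 0.216046 0.786993 0.291148 2.485390 0.000000 0.314730
2.006010 0.251849 0.196246 0.152335 1.002140 0.301281 0.588731 0.187247 0.118358 7.821300 1.800340 0.305434 2.058450 0.649892 0.314887 0.232739 1.388230 0.365369 0.314730 0.000000
0.086627909 0.043972004 0.039089404 0.057045106 0.019307802 0.036728104 0.058058906 0.083251808 0.024431302 0.048466005 0.086209009 0.062028606 0.019502702 0.038431904 0.045763105 0.069517907 0.061012706 0.014385901 0.035274204 0.070895607
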