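wavelength_nm,irradiance_W_m2_nm
380,1.544795
381,1.551120
382,1.557385
383,1.563590
384,1.569734
385,1.575818
386,1.581841
387,1.587804
388,1.593705
389,1.599546
390,1.605325
391,1.611044
392,1.616702
393,1.622299
394,1.627835
395,1.633310
396,1.638724
397,1.644077
398,1.649368
399,1.654599
400,1.659770
401,1.664879
402,1.669927
403,1.674915
404,1.679842
405,1.684708
406,1.689514
407,1.694260
408,1.698945
409,1.703570
410,1.708135
411,1.712639
412,1.717084
413,1.721469
414,1.725795
415,1.730061
416,1.734267
417,1.738414
418,1.742503
419,1.746532
420,1.750503
421,1.754415
422,1.758268
423,1.762064
424,1.765801
425,1.769480
426,1.773102
427,1.776667
428,1.780174
429,1.783624
430,1.787017
431,1.790353
432,1.793633
433,1.796857
434,1.800025
435,1.803137
436,1.806194
437,1.809195
438,1.812142
439,1.815033
440,1.817870
441,1.820653
442,1.823381
443,1.826056
444,1.828677
445,1.831245
446,1.833759
447,1.836221
448,1.838631
449,1.840988
450,1.843293
451,1.845547
452,1.847749
453,1.849900
454,1.851999
455,1.854049
456,1.856048
457,1.857997
458,1.859896
459,1.861746
460,1.863546
461,1.865298
462,1.867001
463,1.868656
464,1.870263
465,1.871821
466,1.873333
467,1.874797
468,1.876215
469,1.877586
470,1.878910
471,1.880189
472,1.881422
473,1.882610
474,1.883753
475,1.884850
476,1.885904
477,1.886913
478,1.887879
479,1.888800
480,1.889679
481,1.890515
482,1.891308
483,1.892058
484,1.892767
485,1.893434
486,1.894059
487,1.894644
488,1.895187
489,1.895690
490,1.896153
491,1.896576
492,1.896959
493,1.897303
494,1.897608
495,1.897875
496,1.898103
497,1.898292
498,1.898444
499,1.898559
500,1.898636
501,1.898677
502,1.898681
503,1.898648
504,1.898580
505,1.898475
506,1.898336
507,1.898161
508,1.897952
509,1.897708
510,1.897429
511,1.897117
512,1.896772
513,1.896392
514,1.895980
515,1.895535
516,1.895058
517,1.894548
518,1.894006
519,1.893433
520,1.892829
521,1.892193
522,1.891527
523,1.890830
524,1.890103
525,1.889346
526,1.888559
527,1.887743
528,1.886898
529,1.886024
530,1.885121
531,1.884191
532,1.883232
533,1.882245
534,1.881231
535,1.880190
536,1.879122
537,1.878027
538,1.876906
539,1.875759
540,1.874586
541,1.873387
542,1.872163
543,1.870914
544,1.869639
545,1.868341
546,1.867018
547,1.865671
548,1.864300
549,1.862905
550,1.861488
551,1.860047
552,1.858583
553,1.857097
554,1.855588
555,1.854057
556,1.852505
557,1.850930
558,1.849335
559,1.847718
560,1.846080
561,1.844422
562,1.842743
563,1.841044
564,1.839325
565,1.837586
566,1.835828
567,1.834050
568,1.832253
569,1.830438
570,1.828603
571,1.826751
572,1.824880
573,1.822991
574,1.821085
575,1.819160
576,1.817219
577,1.815260
578,1.813285
579,1.811293
580,1.809284
581,1.807259
582,1.805218
583,1.803161
584,1.801088
585,1.799000
586,1.796896
587,1.794778
588,1.792644
589,1.790496
590,1.788333
591,1.786156
592,1.783965
593,1.781760
594,1.779541
595,1.777309
596,1.775063
597,1.772804
598,1.770532
599,1.768248
600,1.765950
601,1.763640
602,1.761318
603,1.758984
604,1.756638
605,1.754280
606,1.751910
607,1.749529
608,1.747137
609,1.744733
610,1.742319
611,1.739894
612,1.737458
613,1.735012
614,1.732556
615,1.730090
616,1.727613
617,1.725127
618,1.722631
619,1.720126
620,1.717611
621,1.715087
622,1.712555
623,1.710013
624,1.707462
625,1.704903
626,1.702336
627,1.699760
628,1.697176
629,1.694585
630,1.691985
631,1.689378
632,1.686763
633,1.684140
634,1.681510
635,1.678873
636,1.676230
637,1.673579
638,1.670921
639,1.668257
640,1.665586
641,1.662909
642,1.660226
643,1.657536
644,1.654841
645,1.652140
646,1.649433
647,1.646720
648,1.644002
649,1.641278
650,1.638549
651,1.635815
652,1.633076
653,1.630333
654,1.627584
655,1.624830
656,1.622072
657,1.619310
658,1.616543
659,1.613772
660,1.610997
661,1.608218
662,1.605435
663,1.602648
664,1.599858
665,1.597063
666,1.594266
667,1.591465
668,1.588660
669,1.585853
670,1.583042
671,1.580228
672,1.577412
673,1.574592
674,1.571770
675,1.568946
676,1.566118
677,1.563289
678,1.560457
679,1.557623
680,1.554786
681,1.551948
682,1.549107
683,1.546265
684,1.543421
685,1.540575
686,1.537728
687,1.534878
688,1.532028
689,1.529176
690,1.526323
691,1.523468
692,1.520613
693,1.517756
694,1.514898
695,1.512040
696,1.509181
697,1.506320
698,1.503459
699,1.500598
700,1.497736
701,1.494874
702,1.492011
703,1.489148
704,1.486284
705,1.483420
706,1.480557
707,1.477693
708,1.474829
709,1.471965
710,1.469102
711,1.466239
712,1.463376
713,1.460513
714,1.457651
715,1.454789
716,1.451927
717,1.449067
718,1.446207
719,1.443347
720,1.440489
721,1.437631
722,1.434774
723,1.431919
724,1.429064
725,1.426210
726,1.423357
727,1.420506
728,1.417655
729,1.414806
730,1.411959
731,1.409112
732,1.406267
733,1.403424
734,1.400582
735,1.397742
736,1.394903
737,1.392066
738,1.389231
739,1.386397
740,1.383566
741,1.380736
742,1.377908
743,1.375082
744,1.372258
745,1.369437
746,1.366617
747,1.363799
748,1.360984
749,1.358170
750,1.355360
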