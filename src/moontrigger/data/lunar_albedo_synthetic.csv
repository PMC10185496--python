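wavelength_nm,albedo
380,0.076000
381,0.076200
382,0.076400
383,0.076600
384,0.076800
385,0.077000
386,0.077200
387,0.077400
388,0.077600
389,0.077800
390,0.078000
391,0.078200
392,0.078400
393,0.078600
394,0.078800
395,0.079000
396,0.079200
397,0.079400
398,0.079600
399,0.079800
400,0.080000
401,0.080200
402,0.080400
403,0.080600
404,0.080800
405,0.081000
406,0.081200
407,0.081400
408,0.081600
409,0.081800
410,0.082000
411,0.082200
412,0.082400
413,0.082600
414,0.082800
415,0.083000
416,0.083200
417,0.083400
418,0.083600
419,0.083800
420,0.084000
421,0.084200
422,0.084400
423,0.084600
424,0.084800
425,0.085000
426,0.085200
427,0.085400
428,0.085600
429,0.085800
430,0.086000
431,0.086200
432,0.086400
433,0.086600
434,0.086800
435,0.087000
436,0.087200
437,0.087400
438,0.087600
439,0.087800
440,0.088000
441,0.088200
442,0.088400
443,0.088600
444,0.088800
445,0.089000
446,0.089200
447,0.089400
448,0.089600
449,0.089800
450,0.090000
451,0.090200
452,0.090400
453,0.090600
454,0.090800
455,0.091000
456,0.091200
457,0.091400
458,0.091600
459,0.091800
460,0.092000
461,0.092200
462,0.092400
463,0.092600
464,0.092800
465,0.093000
466,0.093200
467,0.093400
468,0.093600
469,0.093800
470,0.094000
471,0.094200
472,0.094400
473,0.094600
474,0.094800
475,0.095000
476,0.095200
477,0.095400
478,0.095600
479,0.095800
480,0.096000
481,0.096200
482,0.096400
483,0.096600
484,0.096800
485,0.097000
486,0.097200
487,0.097400
488,0.097600
489,0.097800
490,0.098000
491,0.098200
492,0.098400
493,0.098600
494,0.098800
495,0.099000
496,0.099200
497,0.099400
498,0.099600
499,0.099800
500,0.100000
501,0.100200
502,0.100400
503,0.100600
504,0.100800
505,0.101000
506,0.101200
507,0.101400
508,0.101600
509,0.101800
510,0.102000
511,0.102200
512,0.102400
513,0.102600
514,0.102800
515,0.103000
516,0.103200
517,0.103400
518,0.103600
519,0.103800
520,0.104000
521,0.104200
522,0.104400
523,0.104600
524,0.104800
525,0.105000
526,0.105200
527,0.105400
528,0.105600
529,0.105800
530,0.106000
531,0.106200
532,0.106400
533,0.106600
534,0.106800
535,0.107000
536,0.107200
537,0.107400
538,0.107600
539,0.107800
540,0.108000
541,0.108200
542,0.108400
543,0.108600
544,0.108800
545,0.109000
546,0.109200
547,0.109400
548,0.109600
549,0.109800
550,0.110000
551,0.110200
552,0.110400
553,0.110600
554,0.110800
555,0.111000
556,0.111200
557,0.111400
558,0.111600
559,0.111800
560,0.112000
561,0.112200
562,0.112400
563,0.112600
564,0.112800
565,0.113000
566,0.113200
567,0.113400
568,0.113600
569,0.113800
570,0.114000
571,0.114200
572,0.114400
573,0.114600
574,0.114800
575,0.115000
576,0.115200
577,0.115400
578,0.115600
579,0.115800
580,0.116000
581,0.116200
582,0.116400
583,0.116600
584,0.116800
585,0.117000
586,0.117200
587,0.117400
588,0.117600
589,0.117800
590,0.118000
591,0.118200
592,0.118400
593,0.118600
594,0.118800
595,0.119000
596,0.119200
597,0.119400
598,0.119600
599,0.119800
600,0.120000
601,0.120200
602,0.120400
603,0.120600
604,0.120800
605,0.121000
606,0.121200
607,0.121400
608,0.121600
609,0.121800
610,0.122000
611,0.122200
612,0.122400
613,0.122600
614,0.122800
615,0.123000
616,0.123200
617,0.123400
618,0.123600
619,0.123800
620,0.124000
621,0.124200
622,0.124400
623,0.124600
624,0.124800
625,0.125000
626,0.125200
627,0.125400
628,0.125600
629,0.125800
630,0.126000
631,0.126200
632,0.126400
633,0.126600
634,0.126800
635,0.127000
636,0.127200
637,0.127400
638,0.127600
639,0.127800
640,0.128000
641,0.128200
642,0.128400
643,0.128600
644,0.128800
645,0.129000
646,0.129200
647,0.129400
648,0.129600
649,0.129800
650,0.130000
651,0.130200
652,0.130400
653,0.130600
654,0.130800
655,0.131000
656,0.131200
657,0.131400
658,0.131600
659,0.131800
660,0.132000
661,0.132200
662,0.132400
663,0.132600
664,0.132800
665,0.133000
666,0.133200
667,0.133400
668,0.133600
669,0.133800
670,0.134000
671,0.134200
672,0.134400
673,0.134600
674,0.134800
675,0.135000
676,0.135200
677,0.135400
678,0.135600
679,0.135800
680,0.136000
681,0.136200
682,0.136400
683,0.136600
684,0.136800
685,0.137000
686,0.137200
687,0.137400
688,0.137600
689,0.137800
690,0.138000
691,0.138200
692,0.138400
693,0.138600
694,0.138800
695,0.139000
696,0.139200
697,0.139400
698,0.139600
699,0.139800
700,0.140000
701,0.140200
702,0.140400
703,0.140600
704,0.140800
705,0.141000
706,0.141200
707,0.141400
708,0.141600
709,0.141800
710,0.142000
711,0.142200
712,0.142400
713,0.142600
714,0.142800
715,0.143000
716,0.143200
717,0.143400
718,0.143600
719,0.143800
720,0.144000
721,0.144200
722,0.144400
723,0.144600
724,0.144800
725,0.145000
726,0.145200
727,0.145400
728,0.145600
729,0.145800
730,0.146000
731,0.146200
732,0.146400
733,0.146600
734,0.146800
735,0.147000
736,0.147200
737,0.147400
738,0.147600
739,0.147800
740,0.148000
741,0.148200
742,0.148400
743,0.148600
744,0.148800
745,0.149000
746,0.149200
747,0.149400
748,0.149600
749,0.149800
750,0.150000
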