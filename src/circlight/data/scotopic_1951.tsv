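# CIE 1951 scotopic luminous efficiency V'(lambda).
# Published 5-nm values plus the 507-nm unit maximum, pchip to 1 nm.
# wavelength_nm	value
380	0.000589
381	0.000649585
382	0.000736796
383	0.000845614
384	0.000971022
385	0.001108
386	0.00126501
387	0.00145376
388	0.0016741
389	0.0019259
390	0.002209
391	0.0025417
392	0.0029415
393	0.00340704
394	0.00393699
395	0.00453
396	0.00522347
397	0.0060519
398	0.0070096
399	0.00809086
400	0.00929
401	0.0106766
402	0.0123114
403	0.0141761
404	0.0162518
405	0.01852
406	0.0210891
407	0.0240502
408	0.0273587
409	0.0309702
410	0.03484
411	0.0390893
412	0.0438292
413	0.0490005
414	0.0545439
415	0.0604
416	0.0666914
417	0.0735308
418	0.0808446
419	0.088559
420	0.0966
421	0.105085
422	0.114119
423	0.123611
424	0.133468
425	0.1436
426	0.1541
427	0.165064
428	0.176397
429	0.188006
430	0.1998
431	0.211856
432	0.22425
433	0.236887
434	0.249669
435	0.2625
436	0.27544
437	0.288555
438	0.301761
439	0.314971
440	0.3281
441	0.341189
442	0.354295
443	0.367357
444	0.380313
445	0.3931
446	0.405738
447	0.418271
448	0.430675
449	0.442926
450	0.455
451	0.466908
452	0.478671
453	0.490279
454	0.501726
455	0.513
456	0.524063
457	0.534926
458	0.545658
459	0.556326
460	0.567
461	0.577617
462	0.588131
463	0.598637
464	0.609229
465	0.62
466	0.630971
467	0.642084
468	0.653311
469	0.664625
470	0.676
471	0.687454
472	0.699006
473	0.710631
474	0.722304
475	0.734
476	0.745752
477	0.757576
478	0.769424
479	0.781248
480	0.793
481	0.804747
482	0.816522
483	0.828224
484	0.83975
485	0.851
486	0.862044
487	0.872959
488	0.883652
489	0.89403
490	0.904
491	0.913692
492	0.923194
493	0.93235
494	0.941004
495	0.949
496	0.956616
497	0.96403
498	0.970936
499	0.977028
500	0.982
501	0.986196
502	0.990055
503	0.993416
504	0.996118
505	0.998
506	0.999354
507	1
508	0.999566
509	0.998466
510	0.997
511	0.994629
512	0.990866
513	0.986089
514	0.980674
515	0.975
516	0.968689
517	0.961279
518	0.953024
519	0.94418
520	0.935
521	0.92531
522	0.914847
523	0.903728
524	0.892073
525	0.88
526	0.867332
527	0.853927
528	0.839956
529	0.82559
530	0.811
531	0.796089
532	0.78072
533	0.765007
534	0.749063
535	0.733
536	0.716777
537	0.700313
538	0.68366
539	0.666871
540	0.65
541	0.632947
542	0.615673
543	0.598327
544	0.581053
545	0.564
546	0.547146
547	0.530391
548	0.513763
549	0.497291
550	0.481
551	0.464854
552	0.44883
553	0.432979
554	0.417352
555	0.402
556	0.386862
557	0.371896
558	0.357179
559	0.342788
560	0.3288
561	0.315173
562	0.301836
563	0.288822
564	0.276166
565	0.2639
566	0.251974
567	0.240341
568	0.229041
569	0.218114
570	0.2076
571	0.197452
572	0.187612
573	0.178106
574	0.16896
575	0.1602
576	0.151778
577	0.143644
578	0.135821
579	0.128332
580	0.1212
581	0.114377
582	0.107814
583	0.101533
584	0.095554
585	0.0899
586	0.0845278
587	0.0793888
588	0.0744959
589	0.069862
590	0.0655
591	0.0613696
592	0.057431
593	0.0536976
594	0.0501828
595	0.0469
596	0.0438173
597	0.0408967
598	0.0381424
599	0.0355587
600	0.03315
601	0.0308902
602	0.0287533
603	0.0267432
604	0.0248641
605	0.02312
606	0.02149
607	0.0199526
608	0.0185111
609	0.0171691
610	0.01593
611	0.0147779
612	0.0136956
613	0.0126844
614	0.0117455
615	0.01088
616	0.0100761
617	0.00932178
618	0.00861845
619	0.00796741
620	0.00737
621	0.00681774
622	0.00630141
623	0.0058212
624	0.00537733
625	0.00497
626	0.00459309
627	0.00424066
628	0.00391319
629	0.00361114
630	0.003335
631	0.00308053
632	0.00284322
633	0.00262315
634	0.00242038
635	0.002235
636	0.00206407
637	0.0019047
638	0.00175699
639	0.00162106
640	0.001497
641	0.00138286
642	0.00127658
643	0.00117818
644	0.00108766
645	0.001005
646	0.000928889
647	0.00085801
648	0.000792387
649	0.000732042
650	0.000677
651	0.000626401
652	0.000579343
653	0.000535785
654	0.000495684
655	0.000459
656	0.000425173
657	0.000393662
658	0.000364456
659	0.000337539
660	0.0003129
661	0.000290174
662	0.000268997
663	0.000249353
664	0.000231226
665	0.0002146
666	0.000199238
667	0.000184906
668	0.000171596
669	0.000159297
670	0.000148
671	0.000137548
672	0.000127788
673	0.000118713
674	0.000110319
675	0.0001026
676	9.5452e-05
677	8.87712e-05
678	8.25545e-05
679	7.67985e-05
680	7.15e-05
681	6.65884e-05
682	6.19941e-05
683	5.77156e-05
684	5.37514e-05
685	5.01e-05
686	4.67156e-05
687	4.35507e-05
688	4.06009e-05
689	3.78621e-05
690	3.533e-05
691	3.29731e-05
692	3.07627e-05
693	2.86986e-05
694	2.67811e-05
695	2.501e-05
696	2.33641e-05
697	2.18212e-05
698	2.03803e-05
699	1.90402e-05
700	1.78e-05
701	1.66452e-05
702	1.55616e-05
703	1.45484e-05
704	1.36048e-05
705	1.273e-05
706	1.19138e-05
707	1.11466e-05
708	1.04286e-05
709	9.75966e-06
710	9.14e-06
711	8.56289e-06
712	8.02108e-06
713	7.51383e-06
714	7.04039e-06
715	6.6e-06
716	6.18778e-06
717	5.79947e-06
718	5.43527e-06
719	5.09538e-06
720	4.78e-06
721	4.48585e-06
722	4.20932e-06
723	3.95005e-06
724	3.70772e-06
725	3.482e-06
726	3.27056e-06
727	3.07127e-06
728	2.8841e-06
729	2.70902e-06
730	2.546e-06
731	2.39341e-06
732	2.24961e-06
733	2.1145e-06
734	1.98799e-06
735	1.87e-06
736	1.75935e-06
737	1.65494e-06
738	1.55676e-06
739	1.46478e-06
740	1.379e-06
741	1.29863e-06
742	1.22282e-06
743	1.15149e-06
744	1.08458e-06
745	1.022e-06
746	9.63182e-07
747	9.07595e-07
748	8.55218e-07
749	8.06028e-07
750	7.6e-07
751	7.16713e-07
752	6.75765e-07
753	6.37159e-07
754	6.00903e-07
755	5.67e-07
756	5.35152e-07
757	5.05045e-07
758	4.76662e-07
759	4.49986e-07
760	4.25e-07
761	4.01512e-07
762	3.79311e-07
763	3.58354e-07
764	3.38598e-07
765	3.2e-07
766	3.02384e-07
767	2.8563e-07
768	2.69785e-07
769	2.54893e-07
770	2.41e-07
771	2.28007e-07
772	2.15756e-07
773	2.042e-07
774	1.93297e-07
775	1.83e-07
776	1.73203e-07
777	1.63858e-07
778	1.55012e-07
779	1.46711e-07
780	1.39e-07
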