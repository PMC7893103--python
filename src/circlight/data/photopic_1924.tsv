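# CIE 1924 2-deg photopic luminous efficiency V(lambda).
# Published 5-nm values, monotone-cubic (pchip) interpolated to 1 nm.
# wavelength_nm	value
380	4e-05
381	4.112e-05
382	4.416e-05
383	4.864e-05
384	5.408e-05
385	6e-05
386	6.768e-05
387	7.824e-05
388	9.096e-05
389	0.00010512
390	0.00012
391	0.000135886
392	0.000153657
393	0.000173486
394	0.000195543
395	0.00022
396	0.000248594
397	0.000282126
398	0.00031936
399	0.000359063
400	0.0004
401	0.000440483
402	0.000481676
403	0.000526629
404	0.000578387
405	0.00064
406	0.000719538
407	0.000820347
408	0.000938387
409	0.00106962
410	0.00121
411	0.00136229
412	0.00153335
413	0.00172526
414	0.00194011
415	0.00218
416	0.00245619
417	0.00277765
418	0.00314301
419	0.00355092
420	0.004
421	0.00452401
422	0.00514095
423	0.0058259
424	0.0065539
425	0.0073
426	0.00807402
427	0.00889785
428	0.00976467
429	0.0106677
430	0.0116
431	0.0125684
432	0.0135811
433	0.0146335
434	0.0157213
435	0.01684
436	0.0179986
437	0.0192032
438	0.0204445
439	0.0217132
440	0.023
441	0.0242967
442	0.0256107
443	0.0269564
444	0.028348
445	0.0298
446	0.0313161
447	0.0328919
448	0.0345297
449	0.0362317
450	0.038
451	0.0398443
452	0.0417703
453	0.0437741
454	0.045852
455	0.048
456	0.0502322
457	0.0525584
458	0.0549685
459	0.0574524
460	0.06
461	0.0626038
462	0.0652762
463	0.0680367
464	0.0709047
465	0.0739
466	0.0770275
467	0.0802872
468	0.0836912
469	0.0872514
470	0.09098
471	0.0949102
472	0.0990554
473	0.103397
474	0.107918
475	0.1126
476	0.117489
477	0.122615
478	0.12794
479	0.133421
480	0.13902
481	0.144694
482	0.15048
483	0.156457
484	0.162704
485	0.1693
486	0.176273
487	0.183612
488	0.191337
489	0.199466
490	0.20802
491	0.217082
492	0.226701
493	0.236848
494	0.247491
495	0.2586
496	0.270213
497	0.282418
498	0.295256
499	0.308769
500	0.323
501	0.338245
502	0.354583
503	0.371728
504	0.389396
505	0.4073
506	0.425519
507	0.444273
508	0.463486
509	0.483087
510	0.503
511	0.523459
512	0.54453
513	0.565891
514	0.587222
515	0.6082
516	0.629102
517	0.650143
518	0.670914
519	0.691004
520	0.71
521	0.727963
522	0.745241
523	0.761858
524	0.777837
525	0.7932
526	0.808083
527	0.822525
528	0.836405
529	0.849603
530	0.862
531	0.873709
532	0.884893
533	0.895509
534	0.905509
535	0.91485
536	0.923672
537	0.932087
538	0.940007
539	0.94734
540	0.954
541	0.96016
542	0.965982
543	0.971353
544	0.976163
545	0.9803
546	0.983992
547	0.987446
548	0.990518
549	0.993067
550	0.99495
551	0.996437
552	0.997809
553	0.998943
554	0.999715
555	1
556	0.999725
557	0.998976
558	0.997864
559	0.996501
560	0.995
561	0.992963
562	0.990072
563	0.986559
564	0.982658
565	0.9786
566	0.974222
567	0.969273
568	0.963852
569	0.958061
570	0.952
571	0.945547
572	0.938571
573	0.931162
574	0.923408
575	0.9154
576	0.907065
577	0.898307
578	0.889175
579	0.879723
580	0.87
581	0.859921
582	0.849423
583	0.838595
584	0.827525
585	0.8163
586	0.80486
587	0.793134
588	0.781199
589	0.769129
590	0.757
591	0.744792
592	0.732451
593	0.720005
594	0.707479
595	0.6949
596	0.682242
597	0.669486
598	0.656669
599	0.643828
600	0.631
601	0.618173
602	0.605322
603	0.592466
604	0.579619
605	0.5668
606	0.553982
607	0.541154
608	0.528355
609	0.515624
610	0.503
611	0.490488
612	0.47806
613	0.465709
614	0.453425
615	0.4412
616	0.429056
617	0.416997
618	0.40499
619	0.393002
620	0.381
621	0.368921
622	0.356787
623	0.344692
624	0.332732
625	0.321
626	0.309415
627	0.297908
628	0.286594
629	0.275587
630	0.265
631	0.254825
632	0.244961
633	0.235385
634	0.226072
635	0.217
636	0.208153
637	0.199531
638	0.191132
639	0.182956
640	0.175
641	0.167232
642	0.159639
643	0.15225
644	0.145094
645	0.1382
646	0.131529
647	0.125043
648	0.118773
649	0.112749
650	0.107
651	0.101502
652	0.0962108
653	0.0911285
654	0.0862575
655	0.0816
656	0.0771304
657	0.0728272
658	0.0686987
659	0.0647535
660	0.061
661	0.0574091
662	0.0539563
663	0.0506569
664	0.0475264
665	0.04458
666	0.0417796
667	0.0390946
668	0.0365518
669	0.034178
670	0.032
671	0.029992
672	0.0281095
673	0.026351
674	0.024715
675	0.0232
676	0.0218027
677	0.0205062
678	0.0192882
679	0.0181268
680	0.017
681	0.0158941
682	0.0148194
683	0.0137896
684	0.0128185
685	0.01192
686	0.0110806
687	0.0102824
688	0.00953306
689	0.00883978
690	0.00821
691	0.007633
692	0.00709419
693	0.00659519
694	0.00613759
695	0.005723
696	0.00534674
697	0.00500044
698	0.00468017
699	0.004382
700	0.004102
701	0.00383707
702	0.00358696
703	0.00335201
704	0.00313257
705	0.002929
706	0.00273924
707	0.00256084
708	0.00239351
709	0.00223699
710	0.002091
711	0.00195402
712	0.00182474
713	0.00170325
714	0.00158964
715	0.001484
716	0.00138505
717	0.00129162
718	0.00120397
719	0.00112235
720	0.001047
721	0.000977112
722	0.00091161
723	0.000850352
724	0.000793196
725	0.00074
726	0.000690218
727	0.000643371
728	0.000599415
729	0.000558305
730	0.00052
731	0.000484042
732	0.000450068
733	0.000418172
734	0.000388451
735	0.000361
736	0.00033545
737	0.000311412
738	0.000288949
739	0.000268124
740	0.000249
741	0.000231297
742	0.000214714
743	0.000199282
744	0.000185034
745	0.000172
746	0.000159985
747	0.000148773
748	0.000138369
749	0.000128777
750	0.00012
751	0.000111938
752	0.000104455
753	9.75034e-05
754	9.10345e-05
755	8.5e-05
756	7.93778e-05
757	7.41333e-05
758	6.92e-05
759	6.45111e-05
760	6e-05
761	5.55022e-05
762	5.104e-05
763	4.68267e-05
764	4.30756e-05
765	4e-05
766	3.75733e-05
767	3.552e-05
768	3.368e-05
769	3.18933e-05
770	3e-05
771	2.78933e-05
772	2.568e-05
773	2.352e-05
774	2.15733e-05
775	2e-05
776	1.87067e-05
777	1.752e-05
778	1.648e-05
779	1.56267e-05
780	1.5e-05
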