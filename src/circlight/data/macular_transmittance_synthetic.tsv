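# Synthetic macular pigment transmittance 10^(-OD), 2-deg field.
# OD: two-Gaussian shape (main lobe 458 nm, shoulder 485 nm), peak 0.35.
# wavelength_nm	value
380	0.998606
381	0.998364
382	0.998084
383	0.997761
384	0.997389
385	0.996962
386	0.996472
387	0.995911
388	0.995272
389	0.994543
390	0.993716
391	0.99278
392	0.99172
393	0.990526
394	0.989183
395	0.987676
396	0.985989
397	0.984106
398	0.982009
399	0.97968
400	0.977099
401	0.974248
402	0.971106
403	0.967652
404	0.963867
405	0.95973
406	0.955221
407	0.950321
408	0.94501
409	0.939271
410	0.933089
411	0.926449
412	0.919339
413	0.911749
414	0.903673
415	0.895105
416	0.886047
417	0.8765
418	0.866472
419	0.855974
420	0.84502
421	0.83363
422	0.821827
423	0.809639
424	0.797097
425	0.784236
426	0.771095
427	0.757716
428	0.744143
429	0.730424
430	0.716606
431	0.702739
432	0.688875
433	0.675063
434	0.661354
435	0.647798
436	0.634442
437	0.621333
438	0.608514
439	0.596027
440	0.58391
441	0.572198
442	0.560922
443	0.550111
444	0.539788
445	0.529976
446	0.520692
447	0.511948
448	0.503757
449	0.496125
450	0.489057
451	0.482554
452	0.476617
453	0.471241
454	0.466422
455	0.462153
456	0.458426
457	0.455232
458	0.452561
459	0.450403
460	0.448746
461	0.44758
462	0.446896
463	0.446684
464	0.446935
465	0.447642
466	0.4488
467	0.450404
468	0.452453
469	0.454947
470	0.457888
471	0.461279
472	0.465127
473	0.469439
474	0.474227
475	0.479499
476	0.48527
477	0.491553
478	0.498359
479	0.505704
480	0.513598
481	0.522053
482	0.531078
483	0.540678
484	0.550856
485	0.561611
486	0.572936
487	0.584819
488	0.597243
489	0.610183
490	0.623609
491	0.637483
492	0.651761
493	0.666391
494	0.681317
495	0.696476
496	0.711798
497	0.727212
498	0.742643
499	0.758014
500	0.773246
501	0.788264
502	0.802993
503	0.817362
504	0.831306
505	0.844764
506	0.857685
507	0.870023
508	0.881741
509	0.892811
510	0.903213
511	0.912937
512	0.921978
513	0.930342
514	0.93804
515	0.94509
516	0.951514
517	0.95734
518	0.962598
519	0.967322
520	0.971546
521	0.975306
522	0.97864
523	0.981582
524	0.984168
525	0.986433
526	0.988407
527	0.990123
528	0.991608
529	0.992889
530	0.993989
531	0.994933
532	0.995738
533	0.996424
534	0.997005
535	0.997498
536	0.997914
537	0.998264
538	0.998558
539	0.998804
540	0.99901
541	0.999182
542	0.999325
543	0.999444
544	0.999542
545	0.999624
546	0.999691
547	0.999747
548	0.999793
549	0.999831
550	0.999862
551	0.999887
552	0.999908
553	0.999925
554	0.999939
555	0.999951
556	0.99996
557	0.999968
558	0.999974
559	0.999979
560	0.999983
561	0.999986
562	0.999989
563	0.999991
564	0.999993
565	0.999994
566	0.999996
567	0.999996
568	0.999997
569	0.999998
570	0.999998
571	0.999999
572	0.999999
573	0.999999
574	0.999999
575	0.999999
576	1
577	1
578	1
579	1
580	1
581	1
582	1
583	1
584	1
585	1
586	1
587	1
588	1
589	1
590	1
591	1
592	1
593	1
594	1
595	1
596	1
597	1
598	1
599	1
600	1
601	1
602	1
603	1
604	1
605	1
606	1
607	1
608	1
609	1
610	1
611	1
612	1
613	1
614	1
615	1
616	1
617	1
618	1
619	1
620	1
621	1
622	1
623	1
624	1
625	1
626	1
627	1
628	1
629	1
630	1
631	1
632	1
633	1
634	1
635	1
636	1
637	1
638	1
639	1
640	1
641	1
642	1
643	1
644	1
645	1
646	1
647	1
648	1
649	1
650	1
651	1
652	1
653	1
654	1
655	1
656	1
657	1
658	1
659	1
660	1
661	1
662	1
663	1
664	1
665	1
666	1
667	1
668	1
669	1
670	1
671	1
672	1
673	1
674	1
675	1
676	1
677	1
678	1
679	1
680	1
681	1
682	1
683	1
684	1
685	1
686	1
687	1
688	1
689	1
690	1
691	1
692	1
693	1
694	1
695	1
696	1
697	1
698	1
699	1
700	1
701	1
702	1
703	1
704	1
705	1
706	1
707	1
708	1
709	1
710	1
711	1
712	1
713	1
714	1
715	1
716	1
717	1
718	1
719	1
720	1
721	1
722	1
723	1
724	1
725	1
726	1
727	1
728	1
729	1
730	1
731	1
732	1
733	1
734	1
735	1
736	1
737	1
738	1
739	1
740	1
741	1
742	1
743	1
744	1
745	1
746	1
747	1
748	1
749	1
750	1
751	1
752	1
753	1
754	1
755	1
756	1
757	1
758	1
759	1
760	1
761	1
762	1
763	1
764	1
765	1
766	1
767	1
768	1
769	1
770	1
771	1
772	1
773	1
774	1
775	1
776	1
777	1
778	1
779	1
780	1
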