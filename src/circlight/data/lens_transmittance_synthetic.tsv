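# Synthetic young-adult crystalline lens transmittance 10^(-OD).
# OD from a two-component tabulation (Pokorny-Smith-Lutze style, age ~32),
# pchip-interpolated knots; short-wavelength end extrapolated smoothly.
# wavelength_nm	value
380	0.000579429
381	0.000704365
382	0.000855637
383	0.00103866
384	0.00125994
385	0.00152726
386	0.00184996
387	0.00223923
388	0.00270843
389	0.00327355
390	0.00395367
391	0.00478812
392	0.00582576
393	0.00710503
394	0.00866579
395	0.0105458
396	0.0127758
397	0.015372
398	0.0183278
399	0.021604
400	0.0251189
401	0.0288904
402	0.0330228
403	0.037528
404	0.0424179
405	0.0477051
406	0.0534043
407	0.0595324
408	0.0661103
409	0.0731634
410	0.0807235
411	0.0888366
412	0.0975252
413	0.106785
414	0.116601
415	0.126949
416	0.137793
417	0.149083
418	0.160757
419	0.172735
420	0.184927
421	0.197473
422	0.210546
423	0.224075
424	0.23797
425	0.252119
426	0.266393
427	0.280637
428	0.294678
429	0.308325
430	0.321366
431	0.334074
432	0.346811
433	0.359482
434	0.371983
435	0.3842
436	0.39601
437	0.407285
438	0.417888
439	0.427679
440	0.436516
441	0.444626
442	0.452337
443	0.459657
444	0.466595
445	0.473167
446	0.479388
447	0.485278
448	0.490858
449	0.496153
450	0.501187
451	0.505908
452	0.510282
453	0.514372
454	0.518242
455	0.521959
456	0.525592
457	0.529214
458	0.532897
459	0.536718
460	0.540754
461	0.545004
462	0.549389
463	0.553874
464	0.558421
465	0.562993
466	0.56755
467	0.572051
468	0.576453
469	0.580714
470	0.58479
471	0.588723
472	0.592587
473	0.59638
474	0.600102
475	0.60375
476	0.607325
477	0.610825
478	0.61425
479	0.617598
480	0.620869
481	0.624038
482	0.627096
483	0.630062
484	0.632959
485	0.635808
486	0.638632
487	0.641452
488	0.644293
489	0.647178
490	0.65013
491	0.653131
492	0.656145
493	0.659174
494	0.662217
495	0.665273
496	0.668344
497	0.671429
498	0.674528
499	0.677642
500	0.680769
501	0.683962
502	0.687247
503	0.690593
504	0.693967
505	0.697335
506	0.700661
507	0.703913
508	0.707053
509	0.710045
510	0.712853
511	0.715492
512	0.718014
513	0.720437
514	0.722779
515	0.725059
516	0.727297
517	0.729511
518	0.731721
519	0.733946
520	0.736207
521	0.73848
522	0.740733
523	0.742969
524	0.745194
525	0.747412
526	0.749629
527	0.751848
528	0.754077
529	0.756318
530	0.758578
531	0.760844
532	0.763106
533	0.765367
534	0.767633
535	0.76991
536	0.772202
537	0.774514
538	0.776852
539	0.779222
540	0.781628
541	0.784084
542	0.786593
543	0.789144
544	0.791726
545	0.794328
546	0.796939
547	0.799546
548	0.802139
549	0.804706
550	0.807235
551	0.809728
552	0.812197
553	0.814649
554	0.817089
555	0.819521
556	0.821952
557	0.824385
558	0.826828
559	0.829286
560	0.831764
561	0.834249
562	0.836729
563	0.839208
564	0.841693
565	0.844189
566	0.846702
567	0.849238
568	0.851801
569	0.8544
570	0.857038
571	0.859731
572	0.862482
573	0.86528
574	0.868111
575	0.870964
576	0.873826
577	0.876685
578	0.879528
579	0.882343
580	0.885116
581	0.887849
582	0.890557
583	0.893245
584	0.89592
585	0.898587
586	0.901252
587	0.903921
588	0.906599
589	0.909294
590	0.912011
591	0.914736
592	0.917455
593	0.920173
594	0.922898
595	0.925635
596	0.92839
597	0.931171
598	0.933982
599	0.93683
600	0.939723
601	0.942676
602	0.945693
603	0.94876
604	0.951864
605	0.954993
606	0.958131
607	0.961266
608	0.964384
609	0.96747
610	0.97051
611	0.973769
612	0.977412
613	0.981273
614	0.985184
615	0.988975
616	0.992472
617	0.9955
618	0.997883
619	0.999441
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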