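# Synthetic stand-in for a 2-deg corneal S-cone fundamental
# (energy units, peak-normalized; Stockman-Sharpe-like shape).
# Includes lens and macular screening, i.e. as measured at the cornea.
# wavelength_nm	value
380	0.16
381	0.167218
382	0.174853
383	0.18288
384	0.191271
385	0.2
386	0.20892
387	0.218092
388	0.227805
389	0.238345
390	0.25
391	0.263486
392	0.27889
393	0.29555
394	0.312807
395	0.33
396	0.347171
397	0.364783
398	0.38281
399	0.401224
400	0.42
401	0.439326
402	0.459242
403	0.479495
404	0.499832
405	0.52
406	0.54
407	0.56
408	0.58
409	0.6
410	0.62
411	0.640168
412	0.660505
413	0.680758
414	0.700674
415	0.72
416	0.738966
417	0.757762
418	0.776075
419	0.793592
420	0.81
421	0.825292
422	0.839777
423	0.853615
424	0.866969
425	0.88
426	0.892975
427	0.905817
428	0.918171
429	0.929684
430	0.94
431	0.949451
432	0.958432
433	0.966688
434	0.973963
435	0.98
436	0.985493
437	0.99088
438	0.99552
439	0.998773
440	1
441	0.99816
442	0.99328
443	0.98632
444	0.97824
445	0.97
446	0.960944
447	0.950032
448	0.937648
449	0.924176
450	0.91
451	0.894456
452	0.877047
453	0.85841
454	0.839182
455	0.82
456	0.800826
457	0.781215
458	0.761191
459	0.740778
460	0.72
461	0.69867
462	0.676754
463	0.654503
464	0.632168
465	0.61
466	0.587832
467	0.565497
468	0.543246
469	0.52133
470	0.5
471	0.479222
472	0.458809
473	0.438785
474	0.419174
475	0.4
476	0.381224
477	0.36281
478	0.344783
479	0.327171
480	0.31
481	0.293133
482	0.276528
483	0.260357
484	0.24479
485	0.23
486	0.215868
487	0.202218
488	0.189134
489	0.1767
490	0.165
491	0.153926
492	0.143344
493	0.133298
494	0.123835
495	0.115
496	0.106686
497	0.0987837
498	0.091339
499	0.0843962
500	0.078
501	0.0720676
502	0.0664925
503	0.0612835
504	0.0564496
505	0.052
506	0.0478659
507	0.0439831
508	0.0403674
509	0.0370345
510	0.034
511	0.031216
512	0.028624
513	0.026224
514	0.024016
515	0.022
516	0.0201478
517	0.0184274
518	0.0168331
519	0.0153592
520	0.014
521	0.0127256
522	0.0115213
523	0.0104042
524	0.00939141
525	0.0085
526	0.0077085
527	0.00698349
528	0.00632424
529	0.00572999
530	0.0052
531	0.00472363
532	0.00428863
533	0.00389181
534	0.00353
535	0.0032
536	0.00289222
537	0.00260285
538	0.00233737
539	0.00210126
540	0.0019
541	0.00172939
542	0.00157856
543	0.00144304
544	0.00131835
545	0.0012
546	0.00108482
547	0.000974462
548	0.000871692
549	0.000779282
550	0.0007
551	0.000631701
552	0.000570057
553	0.000514562
554	0.000464712
555	0.00042
556	0.000379007
557	0.000340994
558	0.000306478
559	0.000275975
560	0.00025
561	0.000227879
562	0.000208284
563	0.00019075
564	0.00017481
565	0.00016
566	0.00014608
567	0.00013312
568	0.00012112
569	0.00011008
570	0.0001
571	9.05493e-05
572	8.1568e-05
573	7.3312e-05
574	6.60373e-05
575	6e-05
576	5.50119e-05
577	5.06358e-05
578	4.67537e-05
579	4.32477e-05
580	4e-05
581	3.68612e-05
582	3.37814e-05
583	3.07917e-05
584	2.79232e-05
585	2.5207e-05
586	2.26743e-05
587	2.03561e-05
588	1.82836e-05
589	1.64878e-05
590	1.5e-05
591	1.37141e-05
592	1.25055e-05
593	1.13773e-05
594	1.03329e-05
595	9.3752e-06
596	8.50753e-06
597	7.733e-06
598	7.0548e-06
599	6.47607e-06
600	6e-06
601	5.58333e-06
602	5.18102e-06
603	4.7935e-06
604	4.42121e-06
605	4.06462e-06
606	3.72414e-06
607	3.40025e-06
608	3.09337e-06
609	2.80395e-06
610	2.53244e-06
611	2.27928e-06
612	2.04491e-06
613	1.82979e-06
614	1.63435e-06
615	1.45904e-06
616	1.3043e-06
617	1.17059e-06
618	1.05834e-06
619	9.67991e-07
620	9e-07
621	8.44115e-07
622	7.89807e-07
623	7.371e-07
624	6.86015e-07
625	6.36574e-07
626	5.888e-07
627	5.42715e-07
628	4.98341e-07
629	4.557e-07
630	4.14815e-07
631	3.75707e-07
632	3.384e-07
633	3.02915e-07
634	2.69274e-07
635	2.375e-07
636	2.07615e-07
637	1.79641e-07
638	1.536e-07
639	1.29515e-07
640	1.07407e-07
641	8.73e-08
642	6.92148e-08
643	5.31741e-08
644	3.92e-08
645	2.73148e-08
646	1.75407e-08
647	9.9e-09
648	4.41481e-09
649	1.10741e-09
650	0
651	0
652	0
653	0
654	0
655	0
656	0
657	0
658	0
659	0
660	0
661	0
662	0
663	0
664	0
665	0
666	0
667	0
668	0
669	0
670	0
671	0
672	0
673	0
674	0
675	0
676	0
677	0
678	0
679	0
680	0
681	0
682	0
683	0
684	0
685	0
686	0
687	0
688	0
689	0
690	0
691	0
692	0
693	0
694	0
695	0
696	0
697	0
698	0
699	0
700	0
701	0
702	0
703	0
704	0
705	0
706	0
707	0
708	0
709	0
710	0
711	0
712	0
713	0
714	0
715	0
716	0
717	0
718	0
719	0
720	0
721	0
722	0
723	0
724	0
725	0
726	0
727	0
728	0
729	0
730	0
731	0
732	0
733	0
734	0
735	0
736	0
737	0
738	0
739	0
740	0
741	0
742	0
743	0
744	0
745	0
746	0
747	0
748	0
749	0
750	0
751	0
752	0
753	0
754	0
755	0
756	0
757	0
758	0
759	0
760	0
761	0
762	0
763	0
764	0
765	0
766	0
767	0
768	0
769	0
770	0
771	0
772	0
773	0
774	0
775	0
776	0
777	0
778	0
779	0
780	0
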