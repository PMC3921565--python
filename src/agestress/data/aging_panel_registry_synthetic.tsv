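gene	prior_direction
Gfap	up
Vim	up
S100b	up
Apoe	up
Clu	up
Cst3	up
C1qa	up
C1qb	up
C1qc	up
C2	up
C3	up
C4a	up
C4b	up
C1s	up
C1r	up
Cfh	up
Cd74	up
Cd68	up
Cd48	up
Cd53	up
Cd9	up
Cd37	up
Cd63	up
Cd83	up
Cd86	up
B2m	up
RT1-A2	up
RT1-Ba	up
RT1-Bb	up
RT1-Da	up
RT1-Db1	up
Tyrobp	up
Trem2	up
Fcgr2b	up
Fcgr3a	up
Fcer1g	up
Itgam	up
Itgb2	up
Aif1	up
Cx3cr1	up
Csf1r	up
Ctss	up
Ctsb	up
Ctsd	up
Ctsl	up
Ctsz	up
Ctsh	up
Hexa	up
Hexb	up
Lyz2	up
Laptm5	up
Lgals3	up
Lgals3bp	up
Lgals1	up
Mpeg1	up
Npc2	up
Grn	up
Gpnmb	up
Serpina3n	up
Serping1	up
A2m	up
Stat1	up
Stat3	up
Irf7	up
Ifitm3	up
Isg15	up
Oas1	up
Mx1	up
Bst2	up
Psmb8	up
Psmb9	up
Tap1	up
Tapbp	up
Tgfb1	up
Tgfbr2	up
Il18	up
Il33	up
Tnfrsf1a	up
Tlr2	up
Tlr4	up
Nfkbia	up
Socs3	up
Cebpb	up
Cebpd	up
Anxa2	up
Anxa3	up
Anxa5	up
S100a4	up
S100a6	up
Emp3	up
Msn	up
Cd44	up
Vcam1	up
Icam1	up
Timp1	up
Sparc	up
Spp1	up
Dbi	up
Hspb1	up
Cryab	up
Mt1a	up
Snap25	down
Syt1	down
Syt4	down
Syn1	down
Syn2	down
Sv2b	down
Syp	down
Vamp2	down
Cplx1	down
Cplx2	down
Rab3a	down
Stx1a	down
Nrgn	down
Calb1	down
Calb2	down
Pvalb	down
Camk2a	down
Camk2b	down
Camk4	down
Gap43	down
Nefl	down
Nefm	down
Nefh	down
Dlg2	down
Dlg4	down
Homer1	down
Shank1	down
Grin1	down
Grin2a	down
Grin2b	down
Gria1	down
Gria2	down
Gria3	down
Grm5	down
Gabra1	down
Gabra5	down
Gabrb2	down
Gabbr1	down
Gad1	down
Gad2	down
Slc32a1	down
Kcnc1	down
Kcna1	down
Kcnab2	down
Scn1a	down
Scn1b	down
Scn2b	down
Cacna1a	down
Cacnb4	down
Atp2b2	down
Atp1a3	down
Ndrg4	down
Nptx1	down
Ncdn	down
Nsf	down
Stmn2	down
Stmn3	down
Basp1	down
Cck	down
Sst	down
Chga	down
Chgb	down
Scg2	down
Vgf	down
Bdnf	down
Ntrk2	down
Egr1	down
Arc	down
Nr4a1	down
Prkcg	down
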