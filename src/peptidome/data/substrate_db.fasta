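>O35973|Per1|MEROPS Period circadian protein homolog 1
QDALSGSSDLLELLLQEDSRSGTGSAASGSLGSGLGSGSGSGSHEGGSTSASLTRSSQSS
HTSKYFGSLD
>A0A0N4SVZ4|Vwde|SignalP von Willebrand factor D and EGF domain-containing protein
SFDQVDPVQSTFPTETGGLST
>Q8VIJ6|Sfpq|MEROPS Splicing factor proline- and glutamine-rich
TERFGQGGAGPVGGQGPRGMGPGT
>P07724|Alb|MEROPS+SignalP Serum albumin
AEFQPLVEEPKNLVKTNCDLYEKLGEYGFQNARYTQKAPQVSTPTLVEAARNLGRVGTKC
CKAADKDTCFSTEGPNLVTRCKDCSGSLVERRPCFSALTVD
>Q6PDQ2|Chd4|MEROPS Chromodomain-helicase-DNA-binding protein 4
GRPERQFFVKWQGMSYWHCSWVSELQ
>P28481|Col2a1|MEROPS+SignalP Collagen alpha-1(II) chain
PAGANGEKGEVGPPGPSGSTGARGAPGERGETGPPGPAGFAGPPGADGQPGAKGDQGEAG
QKGDAGAPGPQGPSGA
>P08003|Pdia4|MEROPS Protein disulfide-isomerase A4
NKGPVKVVVGKTF
>Q60855|Ripk1|MEROPS Receptor-interacting serine/threonine-protein kinase 1
PPSRSNSEQPGSLHSSQGLQMGPVEESWFSSSPEYPQDENDRSVQAKLQEEASYHAFGL
>Q6ZQ11|Chsy1|SignalP Chondroitin sulfate synthase 1
KCLREMYTTHEDVEVGRCVRRFAGVQCVWSYEMQQLFYENYEQNKKGYLRDL
>G5E8J6|Hrc|SignalP Histidine rich calcium binding protein, isoform CRA_a
KDRGHREEGEDFSREYGHRVQDHRYPG
>Q8VEJ3|Dkk4|SignalP Dickkopf-related protein 4
VCTAVEDTRPVMDRNTDGQDGAYAEGTTKWPAEENRPQGKPSTKKSQSSKGQEGESCLRT
>P09813|Apoa2|SignalP Apolipoprotein A-II
FSSLMNLEEKPAPAA
>L7N1X2|Vmn2r13Vmn2r13|SignalP Protein
TMNNEKYPVNLSETRLGWNSFNCSLSKNSNKKDHFTFNNTLEWTARNNFDMVLSE
>P35689|Ercc5|MEROPS DNA repair protein complementing XP-G cells homolog
ATADAGSLSPRTCAALQKALDDDNDEKVSGSSDDLAEKMLLGSGLEQEEHADETAERGGG
VPFDTSVPKRRRPSGNGGFLGDPYCSESPQESSCEDGEGSSVMSARQRSAAESSKLSCSD
VPDLVR
>P31938|Map2k1|MEROPS Dual specificity mitogen-activated protein kinase kinase 1
KPSGLVMARKLLHLELKPAL
>O55234|Psmb5|MEROPS Proteasome subunit beta type-5
YYVDSEGNRLSGTAFSVGSGSVYAYGVMDRGYSYDLKVEEAYDLARRALYQATYRDAYSG
>P63085|Mapk1|MEROPS Mitogen-activated protein kinase 1
DLKLCDFGLARVADPDHDH
>E9PV24|Fga|MEROPS Fibrinogen alpha chain
GKEAYAEYHFRVGSEAEGYALQVSSY
>Q8K310|Matr3|MEROPS Matrin-3
SLCDLPVHSNKEWSQHLNGASHSRRCQLLLELYPEWNPDNDTGHTMGDPFMLQQSTN
>B2RT14|Ugt1a5|SignalP UDP-glucuronosyltransferase
ELFQREVSSVELFSYA
>Q61001|Lama5|MEROPS Laminin subunit alpha-5
RPCPTEQLSPSHPPLATCFGSDVDLQLEMAVPQPGQYVLVVEYVGEDSHQEMGVAVHTPQ
>G5E8Z7|Vmn2r75|SignalP G3425
YLPSGQQLYMSKEM
>K7N709|Vmn2r47|SignalP Protein Gm10302
SFDWLMEQKFDMTFSENSHNLYNAVHALAHALHEMNLQQADNQALGNGKGASSHCLKVNS
>Q06890|ClusterinClu|MEROPS 
AMDVQLHSPAFQFPDVDFLREGEDDRTVCKELRRNSTGCLKMKGQCEKCQELLSVDCS
>Q61072|Adam9|SignalP Disintegrin and metalloproteinase domain-containing protein 9
KLQCENVQDMPVFG
>Q8K4P0|Wdr33|MEROPS pre-mRNA 3′ end processing protein WDR33
GPQGQFRAPGPQGQMGPQGPPMHQGGGGPQGFMGPQGPQGPPQGLPRPQDMHGPQGMQRH
PGPH
>P23116|Eif3a|MEROPS Eukaryotic translation initiation factor 3 subunit A
KEEEEQRRAEEQMLKERE
>P27641|Xrcc5|MEROPS+SignalP X-ray repair cross-complementing protein 5
ELVVQDGVTLLTKDEGPGSSLT
>O09165|Casq1|SignalP Calsequestrin-1
LNELDFYEAFMEEPMTLPDKPNSEEELVSFVEEHRRSTLRKLKPESMYETWEDD
>P70175|Dlg3|MEROPS Disks large homolog 3
SEFPHKFGSCVPHTTRPRRDNEVDGQDYHFVVSREQMEKDLQDNKFLEAGQFNDNL
>Q03350|Thbs2|MEROPS Thrombospondin-2
QQRGRSCDVTSNTCLGPSLQTRTCSLGKCDTRLRQNGGWSHWSPWSSCSVTCGVGNVTR
>Q8CBF3|Ephb1|MEROPS Ephrin type-B receptor 1
GKMCFQTLTDDDYKSELR
>Q6ZQ03|Fnbp4|MEROPS Formin-binding protein 4
GCYYYWNTQTNEVTWELPQYLATQVQGLQHYQPSSVTGTEAAFVVNTDMYTKERTT
>P70699|Gaa|MEROPS Lysosomal alpha-glucosidase
VPFDGMWLDMNEPSNFVRGSQQGCPNNELENPPYVPGVVGGLLQAATLCASSHQFLSTHY
>P20722|Bmp6|SignalP Bone morphogenetic protein 6
GYAANYCDGECSFPLNAHMNATNHALVQTLVHLMNPEYVPKPCCAPTKLNALSVLYFDD
>E0CXN0|Mst1|SignalP Hepatocyte growth factor-like protein
GSGEQYRGSVSKTRKGVQCQHWSSETPHKPQFTPTSAPQAGLEANFCRNPDGDSHGPWC
>P47753|Capza1|MEROPS F-actin-capping protein subunit alpha-1
SCDSALRAYVKDHYSNGFCTVYAKTLDGQQTLLACLESHQFQPKNFWNGRWRSEW
>Q7TPR4|Actn1|MEROPS Alpha-actinin-1
GNVKMTLGMLWTLL
>P16110|Lgals3|MEROPS Galectin-3
YPGQAPPGAYPGQAPPSAYPGPTAPGAYPGPTAPGAYPGQPAPGAFPGQPGAPGAYPQCS
GGYPAAGPYGV
>B1ARY8|Gm572Gm572|SignalP Protein
TQAFYRVDLSLDFAEMDSPVHWTVE
>Q61282|Acan|MEROPS Aggrecan core protein
VDTSFVEVTPTTFREEEGLGSVELSGFPSGETELSGTSGTVDVSEQSSGALDSSGLTSPT
PEFSGLFGSGQSSGLTSVSGETSGLSDLSG
>Q05186|Rcn1|MEROPS Reticulocalbin-1
FKASDLDGDLTATREEFTAF
>Q9Z0N1|Eif2s3x|MEROPS Eukaryotic translation initiation factor 2 subunit 3 X-linked
LYKLDDPSCPRPECYRSCGSSTPDEFPTDLPGTKGNFKLVRHVSFVDCPGHDLLMATM
>A2APM2|Cd44|SignalP CD44 antigen
ESNTNPTGWEPNEENEDETDKYPSFSGSG
>Q07797|Lgals3bp|MEROPS Galectin-3-binding protein
RYNQLYTYGYGSVARYNSYQSFQTPQHPSFLFKDKQLSWSATYLPTMQSCWNYGF
>Q6P5H2|NestinNes|MEROPS 
KWNPETVESPGGVEDSQQCLEVEEGPEREQHQESLRSLGEVEWELPGSGSQQRWEDVV
>F2YMG0|Prss56|SignalP Serine protease 56
RPSTMLCAGYLAGGLDSCQGDSGGPLTCSEPGPRPREVLFGVTSWGDGCGEPGKPGVYTR
VT
>F7C950|Gm9573Gm9573|SignalP Protein
STPTPTTTASSTASGSAPNPTTTVSSTASGSTPTLPTTASSSGSGSTPTLTTTESSTASG
SSPTLTTTASSSA
>F8VPK8|Pcdh9|SignalP Protein Pcdh9
SDGSSTPARATVTLNVTDVNDN
>A0A0R4J1I6|Nup210|SignalP Nuclear pore membrane glycoprotein 210
FKQDVFDFPACDVFTVEPGFDAALGQYLC
>Q9ESG8|Zdhhc16|SignalP Probable palmitoyltransferase ZDHHC16
VVFVVLVLVLTGSLVALAYLCVLPLLLRTY
>Q9JMH9|IaMyo18a|MEROPS Unconventional myosin-XVII
LTSELTDERNTGESASQLLDAETA
>Q9D554|Sf3a3|MEROPS Splicing factor 3A subunit 3
KARENPSEEAQNLVEFTDE
>E9PX70|Col12a1|SignalP Collagen alpha-1(XII) chain
DLVCSPVWTSRDRCCDLPSRRDEAKCPALPNACTCTQDSVGPPGPPGPAGGPGAKGPRGE
R
>P21981|Tgm2|MEROPS Protein-glutamine gamma-glutamyltransferase 2
RGYEASVDSLTFGAVTGPDPSEEAGTKARFSLSDNVEEGSWSASVLDQQDNVLSLQLCTP
AN
>P54726|Rad23a|MEROPS UV excision repair protein RAD23 homolog A
HPPPTSREDKSPSEESTTTTSPESLSGSVPSSG
>Q5ND28|Scarf1|SignalP Scavenger receptor class F member 1
GRNQASAGSAPGAVLSQAMESTAVRPEETPRGLGDGLESSGTVQEPDAGGSSLEQDSQKQ
AEEKEQ
>Q61048|Wbp4|MEROPS WW domain-binding protein 4
KSQPKKFCDYCKCWLADNRPSVEFHE
>Q61555|Fbn2|MEROPS Fibrillin-2
TDGSFRCECPMGYNLDYTGVRCVDTDE
>Q61730|Il1rap|SignalP Isoform 3 of Interleukin-1 receptor accessory protein
SSERVSGAEPAPGTMSKHRGKPSAACRCCVTYCEGESHLRSKSRAEMHTHPQWETHL
>Q9QZ82|Cyp11a1|MEROPS Cholesterol side-chain cleavage enzyme mitochondrial
LPFKNL
>Q61554|Fbn1|MEROPS Fibrillin-1
NGLCVNSRGSFKCECPNGMTLDATGRLCLDLRLETCFLKYDDEECTLPLAGRHRMDA
>P11276|FibronectinFn1|MEROPS 
NGRLTCTSRNRCNDQDTRTSYRLGDTWSKKDNRGNLLQCVCTGNGRGEWKCERHA
>K7N712|Vmn2r62|SignalP Protein Vmn2r62
TVNPYTYPEDDYLPKFWVFFFKCSFSEFDCQLLENCQPNASLDLLPRHLFDPAMS
>P08121|Col3a1|MEROPS Collagen alpha-1(III) chain
KSGVGGMGGYPGPAGPPGPPGPPGSS
>P16675|Ctsa|MEROPS+SignalP Lysosomal protective protein
SSLDGLLTEHGPFLL
>F8VQL0|Met|SignalP Hepatocyte growth factor receptor
LVSARSVSPTTEMVSNESVDYRATFPEDQFPNSSQNGACRQVQYPLTDLSPLLTSGDSDL
S
>Q62059|Vcan|MEROPS Versican core protein
PFPTFSSTAVMAKETTAFEEGEGSTYTPSEGRLMTGSERVPGLETTPVGTSYPPGALTDQ
EVE
>E9PXI5|Vmn2r23Vmn2r23|SignalP Protein
KLLLAFSLLLVLLLFQEQL
>Q9EPL2|Clstn1|MEROPS+SignalP Calsyntenin-1
ELETSHLGKGCDRDTYSEKSLHRLCGAAAGTSELLPSPSSSFNWTVGLPTDNGHDSDQVF
E
>Q9QZM0|Ubqln2|MEROPS Ubiquilin-2
QATTQPSTTAGTSTTTTTTTTAA
>Q3UEK9|Ahsg|SignalP Alpha-2-HS-glycoprotein
PPASVVVGPVVVPR
>Q7TSK2|Sez6|SignalP Isoform 3 of Seizure protein 6
EEAPQPALPFQPDSPTHFTP
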