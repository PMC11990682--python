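name,formula,compound_class,role,reference_rt,fragments,semi_quant_reference,provenance,flag
gentisic acid,C7H6O4,phenolic acid,suspect,2.60,135.0088;109.0295,gallic acid,olive suspect literature; synthetic RT and fragments,
hydroxytyrosol,C8H10O3,phenol,suspect,2.90,135.0452;109.0659,vanillin,olive suspect literature; synthetic RT and fragments,
oleoside,C16H22O11,secoiridoid,suspect,3.20,371.0984;345.1191,vanillin,olive suspect literature; synthetic RT and fragments,
salidroside,C14H20O7,phenol,suspect,3.45,281.1031;255.1238,vanillin,olive suspect literature; synthetic RT and fragments,
tyrosol,C8H10O2,phenol,suspect,3.50,119.0502;93.0710,vanillin,olive suspect literature; synthetic RT and fragments,
4-hydroxybenzoic acid,C7H6O3,phenolic acid,suspect,3.80,119.0139;93.0346,gallic acid,olive suspect literature; synthetic RT and fragments,
chlorogenic acid,C16H18O9,phenolic acid,suspect,4.10,335.0772;309.0980,gallic acid,olive suspect literature; synthetic RT and fragments,
homovanillic acid,C9H10O4,phenolic acid,suspect,4.35,163.0401;137.0608,gallic acid,olive suspect literature; synthetic RT and fragments,
esculetin,C9H6O4,coumarin,suspect,4.60,159.0088;133.0295,vanillin,olive suspect literature; synthetic RT and fragments,
elenolic acid,C11H14O6,secoiridoid,suspect,5.00,223.0612;197.0819,vanillin,olive suspect literature; synthetic RT and fragments,
verbascoside,C29H36O15,phenol,suspect,6.20,605.1876;579.2083;461.1453,vanillin,olive suspect literature; synthetic RT and fragments,
benzoic acid,C7H6O2,phenolic acid,suspect,6.85,103.0189;77.0397,gallic acid,olive suspect literature; synthetic RT and fragments,
oleuropein,C25H32O13,secoiridoid,suspect,6.90,521.1665;495.1872;377.1242,vanillin,olive suspect literature; synthetic RT and fragments,
olivil,C20H24O7,lignan,suspect,7.10,357.1344;331.1551,vanillin,olive suspect literature; synthetic RT and fragments,
trans-polydatin,C20H22O8,stilbene,suspect,7.20,371.1136;345.1344,quercetin,olive suspect literature; synthetic RT and fragments,
naringin,C27H32O14,flavonoid glycoside,suspect,7.55,561.1614;535.1821;417.1191,rutin,olive suspect literature; synthetic RT and fragments,
hydroxypinoresinol,C20H22O7,lignan,suspect,7.85,355.1187;329.1394,vanillin,olive suspect literature; synthetic RT and fragments,
eriodictyol,C15H12O6,flavonoid,suspect,8.15,269.0455;243.0663,quercetin,olive suspect literature; synthetic RT and fragments,
oleacein,C17H20O6,secoiridoid,suspect,8.20,301.1081;275.1289,vanillin,olive suspect literature; synthetic RT and fragments,
pinoresinol,C20H22O6,lignan,suspect,8.60,339.1238;313.1445,vanillin,olive suspect literature; synthetic RT and fragments,
syringaresinol,C22H26O8,lignan,suspect,8.75,399.1449;373.1657,vanillin,olive suspect literature; synthetic RT and fragments,
oleuropein aglycone,C19H22O8,secoiridoid,suspect,9.00,359.1136;333.1344,vanillin,olive suspect literature; synthetic RT and fragments,
genistein,C15H10O5,flavonoid,suspect,9.35,251.0350;225.0557,quercetin,olive suspect literature; synthetic RT and fragments,
maslinic acid,C30H48O4,triterpenoid,suspect,13.20,453.3374;427.3582,,olive suspect literature; synthetic RT and fragments,no same-class calibration standard; not semi-quantifiable
oleanolic acid,C30H48O3,triterpenoid,suspect,13.60,437.3425;411.3632,,olive suspect literature; synthetic RT and fragments,no same-class calibration standard; not semi-quantifiable
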