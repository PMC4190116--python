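species	flowering_period	pollination	status	Cornisella_I	Cornisella_II	Cornisella_III	Ortanella_I	Ortanella_II	Ortanella_III	AlpeMoncodeno_I	AlpeMoncodeno_II	AlpeMoncodeno_III
Acer sp.	IV-V	both	common	+	+		+	+				
Achillea sp.	VI-IX	entomophilous	common		+	+						
Amelanchier ovalis	IV-V	entomophilous	common				+	+				
Anthyllis vulneraria	IV-VI	entomophilous	common	+			+					
Aquilegia atrata	V-VII	entomophilous	common						+			
Aquilegia brauneana	VI-VII	entomophilous	rare					+	+		+	+
Astrantia major	VI-IX	entomophilous	common					+				
Buphthalmum salicifolium	VI-VII	entomophilous	common									+
Bupleurum petraeum	VII-VIII	entomophilous	rare						+			
Campanula cochleariifolia	VI-VII	entomophilous	common									+
Campanula raineri	VI-VIII	entomophilous	rare								+	+
Campanula scheuchzeri	VII-VIII	entomophilous	common			+						+
Centaurea jacea	VI-VII	entomophilous	common					+				
Centaurea nigrescens	VI-VIII	entomophilous	common		+	+						
Centaurea rhaetica	VI-VII	entomophilous	rare									+
Cirsium erisithales	VI-VIII	entomophilous	common			+						
Clinopodium alpinum	VI-VIII	entomophilous	common							+		
Cyanus triumfettii	V-VIII	entomophilous	common	+	+					+	+	
Cytisus nigricans	VI-VII	entomophilous	common				+					
Dactylorhiza maculata	V-VII	entomophilous	common					+		+	+	+
Fagus sylvatica	V	anemophilous	common	+	+	+	+	+	+	+		
Fraxinus excelsior	III-IV	anemophilous	common				+					
Genista radiata	VI-VII	entomophilous	common						+		+	+
Geranium robertianum	V-X	entomophilous	common	+	+	+	+	+	+			
Hippocrepis comosa	V-VIII	entomophilous	common				+	+				
Horminum pyrenaicum	VII-VIII	entomophilous	common						+			+
Hypericum perforatum	V-VIII	entomophilous	common	+	+							
Leontodon hispidus	VI-X	entomophilous	common				+	+	+			
Lonicera japonica	V-IX	entomophilous	alien						+			
Lotus corniculatus	IV-IX	entomophilous	common	+			+	+	+			
Minuartia grignensis	VI-VIII	entomophilous	rare									+
Noccaea rotundifolia grignensis	VII-VIII	entomophilous	rare									+
Parnassia palustris	VI-VIII	entomophilous	common							+	+	
Pelargonium × hortorum	I-XII	entomophilous	alien				+	+	+			
Physoplexis comosa	VII-VIII	entomophilous	rare						+			
Phyteuma scheuchzeri	VI-VIII	entomophilous	common		+	+		+	+			
Potentilla erecta	V-VIII	entomophilous	common	+			+		+			
Primula grignensis	IV-VII	entomophilous	rare							+		
Prunella grandiflora	VI-VIII	entomophilous	common	+	+	+		+	+	+	+	+
Quercus sp.	IV-V	anemophilous	common				+	+				
Rhododendron sp.	V-VII	entomophilous	common							+	+	+
Rosa canina	V-VII	entomophilous	common	+	+	+	+	+				
Rubus ulmifolius	V-VII	entomophilous	common	+	+	+	+		+			
Salvia pratensis	V-VIII	entomophilous	common		+			+				
Sanguisorba minor	VII-VIII	entomophilous	common						+			
Saxifraga aizoides	VI-VIII	entomophilous	common								+	
Saxifraga caesia	VI-VIII	entomophilous	common							+	+	+
Sorbus aria	V-VI	entomophilous	common				+					
Teucrium montanum	V-VIII	entomophilous	common			+				+	+	
Tragopogon pratensis	V-VIII	entomophilous	common	+	+	+						
Trifolium montanum	V-VIII	entomophilous	common	+	+	+	+	+	+	+	+	+
Xerolekia speciosissima	VI-VII	entomophilous	rare		+					+	+	+
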