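gene	variant	sequence
en	WT	gtagtcaaCTAATTCagtcgttgcgctCGATGtgaacAGACGTgcgtgtc
en	mDPE	gtagtcaaCTAATTCagtcgttgcgctCGATGtgaacCTCATGtcgtgtc
en	mBridgeI	gtagtcaaCTAATTCagtcgttgcgctATCCAtgaacAGACGTgcgtgtc
en	mDPE_27_29	gtagtcaaCTAATTCagtcgttgcgctCGATGtgaagTAACGTgcgtgtc
drm	WT	gtaactttGCAGTTgactctcgcgcacAGAAGcgttcGGAAGTgaaatat
drm	mDPE	gtaactttGCAGTTgactctcgcgcacAGAAGcgttcCTCATGtaaatat
drm	mBridgeI	gtaactttGCAGTTgactctcgcgcacATCCAcgttcGGAAGTgaaatat
drm	mDPE_27_29	gtaactttGCAGTTgactctcgcgcacAGAAGcgttgTAAAGTgaaatat
Sema5c	WT	tggtgggtTCAGTTtcttgcgactcttTGCGCggtcaACTTCGccgatcg
Sema5c	mDPE	tggtgggtTCAGTTtcttgcgactcttTGCGCggtcaCTCATGtcgatcg
Sema5c	mBridgeI	tggtgggtTCAGTTtcttgcgactcttATCCAggtcaACTTCGccgatcg
Sema5c	mDPE_27_29	tggtgggtTCAGTTtcttgcgactcttTGCGCggtcgTATTCGccgatcg
Ppa	WT	ctgcgagtTCAGTTtttctttatcatcCGGTTcgtgcACATCGcgtctcg
Ppa	mDPE	ctgcgagtTCAGTTtttctttatcatcCGGTTcgtgcCTCATGtgtctcg
Ppa	mBridgeI	ctgcgagtTCAGTTtttctttatcatcATCCAcgtgcACATCGcgtctcg
Ppa	mDPE_27_29	ctgcgagtTCAGTTtttctttatcatcCGGTTcgtggTAATCGcgtctcg
Cad74A	WT	aagtccggCCAGAAggtaagcgagcgtCGCTTcgtacAGACGTggtcgcg
Cad74A	mDPE	aagtccggCCAGAAggtaagcgagcgtCGCTTcgtacCTCATGtgtcgcg
Cad74A	mBridgeI	aagtccggCCAGAAggtaagcgagcgtATCCAcgtacAGACGTggtcgcg
Cad74A	mDPE_27_29	aagtccggCCAGAAggtaagcgagcgtCGCTTcgtagTAACGTggtcgcg
noc	WT	cgttgaatTCAATTcgaattttgacttCGCAGcgttcAGACGTgttcgga
noc	mDPE	cgttgaatTCAATTcgaattttgacttCGCAGcgttcCTCATGtttcgga
noc	mBridgeI	cgttgaatTCAATTcgaattttgacttATCCAcgttcAGACGTgttcgga
noc	mDPE_27_29	cgttgaatTCAATTcgaattttgacttCGCAGcgttgTAACGTgttcgga
opa	WT	ggagcattTCAGTCctgctgcgcatctTGAAAcgtcaAGTCTTggcattc
opa	mDPE	ggagcattTCAGTCctgctgcgcatctTGAAAcgtcaCTCATGtgcattc
opa	mBridgeI	ggagcattTCAGTCctgctgcgcatctATCCAcgtcaAGTCTTggcattc
opa	mDPE_27_29	ggagcattTCAGTCctgctgcgcatctTGAAAcgtcgTATCTTggcattc
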