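locus,kit,library,dye,motif,size_min,size_max,scoring_error_pct
Pma036,kit-1,cloning,Atto565,TAGA,328,596,1
Pma043,kit-1,cloning,6FAM,TATC,288,430,0
Pma097,kit-1,cloning,Atto565,ATCT,96,206,0
Pma104,kit-1,cloning,Atto550,TATC,160,266,0
Pma106,kit-1,cloning,HEX,GATA,129,245,0
Pma109,kit-1,cloning,HEX,ATCT,376,460,1
Pma112,kit-1,cloning,6FAM,TATC,136,196,8
Pma114,kit-1,cloning,Atto565,TATC,216,281,0
Pma180,kit-1,genomic,Atto550,AGAT,270,362,0
Ple002,kit-2,genomic,HEX,AGAT,196,284,0
Ple004,kit-2,genomic,6FAM,AAT,366,430,0
Pma012,kit-2,genomic,6FAM,AATG,128,182,0
Pma025,kit-2,genomic,Atto565,ACTC,326,438,0
Pma038,kit-2,genomic,Atto550,AGAT,286,400,0
Pma090,kit-2,cloning,HEX,TAGA,352,408,0
Pma101,kit-2,cloning,6FAM,TATC,246,316,0
Pma412,kit-2,genomic,HEX,ACAT,132,188,0
Ple001,kit-3,genomic,6FAM,ACGC,142,215,1
Ple005,kit-3,genomic,HEX,ACAG,396,452,0
Pma020,kit-3,genomic,Atto550,AGAT,285,399,0
Pma022,kit-3,genomic,HEX,AGAT,278,340,0
Pma027,kit-3,genomic,Atto565,AAAT,280,394,0
Pma121,kit-3,cloning,6FAM,ATAG,361,433,0
Pma191,kit-3,genomic,Atto550,AAAT,174,232,0
Pma288,kit-3,genomic,Atto565,AAAG,140,210,0
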