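gene	chrom	pos
Esr1	chr1	41190056
Esr1	chr1	41190090
Esr1	chr1	41190155
Esr1	chr1	41190176
Esr1	chr1	41190200
Esr1	chr1	41190283
Esr1	chr1	41190310
Esr1	chr1	41190371
Esr1	chr1	41190460
Esr1	chr1	41190482
Esr1	chr1	41190561
Esr1	chr1	41190603
Esr1	chr1	41190622
Esr1	chr1	41190648
Ar	chrX	67656070
Ar	chrX	67656138
Ar	chrX	67656161
Ar	chrX	67656206
Ar	chrX	67656232
Ar	chrX	67656317
Ar	chrX	67656386
Ar	chrX	67656408
Ar	chrX	67656495
Ar	chrX	67656525
Ar	chrX	67656568
Ar	chrX	67656657
Ar	chrX	67656679
Ar	chrX	67656767
Ar	chrX	67656856
Ar	chrX	67656921
Ar	chrX	67656942
Pgr	chr8	55212043
Pgr	chr8	55212063
Pgr	chr8	55212149
Pgr	chr8	55212181
Pgr	chr8	55212233
Pgr	chr8	55212301
Pgr	chr8	55212334
Pgr	chr8	55212418
Pgr	chr8	55212448
Pgr	chr8	55212536
Pgr	chr8	55212590
Pgr	chr8	55212676
Pgr	chr8	55212714
Pgr	chr8	55212742
Pgr	chr8	55212831
Pgr	chr8	55212919
Pgr	chr8	55212958
Pgr	chr8	55213020
Pgr	chr8	55213047
Cxcl12	chr4	150932085
Cxcl12	chr4	150932108
Cxcl12	chr4	150932195
Cxcl12	chr4	150932217
Cxcl12	chr4	150932258
Cxcl12	chr4	150932336
Cxcl12	chr4	150932419
Cxcl12	chr4	150932488
Cxcl12	chr4	150932543
Cxcl12	chr4	150932617
Cd9	chr4	157865089
Cd9	chr4	157865162
Cd9	chr4	157865223
Cd9	chr4	157865276
Cd9	chr4	157865322
Cd9	chr4	157865360
Cd9	chr4	157865406
Cd9	chr4	157865431
Cd9	chr4	157865519
Cd9	chr4	157865572
Bcl11b	chr6	133421082
Bcl11b	chr6	133421160
Bcl11b	chr6	133421218
Bcl11b	chr6	133421290
Bcl11b	chr6	133421341
Bcl11b	chr6	133421365
Bcl11b	chr6	133421395
Bcl11b	chr6	133421475
Bcl11b	chr6	133421543
Bcl11b	chr6	133421579
Mpped2	chr1	175118058
Mpped2	chr1	175118092
Mpped2	chr1	175118169
Mpped2	chr1	175118237
Mpped2	chr1	175118257
Mpped2	chr1	175118281
Mpped2	chr1	175118367
Mpped2	chr1	175118455
Mpped2	chr1	175118510
Mpped2	chr1	175118568
Mpped2	chr1	175118627
Tgm2	chr3	152740078
Tgm2	chr3	152740167
Tgm2	chr3	152740240
Tgm2	chr3	152740263
Tgm2	chr3	152740289
Tgm2	chr3	152740338
Tgm2	chr3	152740413
Tgm2	chr3	152740436
Tgm2	chr3	152740458
Tgm2	chr3	152740512
Tgm2	chr3	152740600
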