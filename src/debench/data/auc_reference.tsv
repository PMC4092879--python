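method	I	II	III	IV	V	VI	VII
DESeq	0.9284	0.7717	0.9097	0.9281	0.8921	0.9326	0.7427
edgeR	0.9322	0.7608	0.9213	0.9323	0.9001	0.9393	0.7336
DEGseq	0.6081	0.6046	0.6413	0.5722	0.6031	0.6131	0.6000
NBPSeq	0.9129	0.7559	0.9209	0.8496	0.8828	0.9206	0.7330
baySeq	0.9280	0.7843	0.9013	0.9240	0.9013	0.9297	0.7660
TSPM	0.8744	0.7341	0.9109	0.7688	0.8505	0.8870	0.7176
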