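((((sce,sba),sca),(cgl,(kpo,zro))),((kth,kwa),(skl,(ago,kla))));
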