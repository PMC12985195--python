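alias	canonical
miR-451a	miR-451a-5p
miR-451	miR-451a-5p
miR-103-3p	miR-103a-3p
miR-107	miR-107-3p
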