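mirna_id	role	brain_enriched
miR-7-5p	tumor_suppressor	true
miR-10b-5p	oncomiR	true
miR-16-5p	tumor_suppressor	true
miR-17-5p	context_dependent	true
miR-18a-5p	oncomiR	false
miR-19b-3p	oncomiR	true
miR-20a-5p	oncomiR	true
miR-21-5p	oncomiR	true
miR-26a-5p	oncomiR	true
miR-29a-3p	context_dependent	true
miR-29b-3p	tumor_suppressor	true
miR-29c-3p	tumor_suppressor	true
miR-30b-5p	context_dependent	true
miR-32-5p	context_dependent	false
miR-34a-5p	tumor_suppressor	false
miR-92a-3p	oncomiR	true
miR-93-5p	context_dependent	false
miR-99a-5p	tumor_suppressor	true
miR-100-5p	tumor_suppressor	true
miR-101-3p	tumor_suppressor	true
miR-103a-3p	tumor_suppressor	true
miR-107-3p	tumor_suppressor	true
miR-125b-5p	oncomiR	true
miR-128-3p	tumor_suppressor	true
miR-136-5p	tumor_suppressor	true
miR-146a-5p	tumor_suppressor	true
miR-146b-5p	tumor_suppressor	false
miR-148a-3p	context_dependent	true
miR-155-5p	oncomiR	false
miR-181a-5p	tumor_suppressor	true
miR-181b-5p	tumor_suppressor	true
miR-181c-5p	tumor_suppressor	true
miR-182-5p	oncomiR	true
miR-204-5p	tumor_suppressor	true
miR-210-3p	oncomiR	true
miR-221-3p	oncomiR	true
miR-222-3p	oncomiR	true
miR-335-5p	oncomiR	true
miR-338-3p	tumor_suppressor	true
miR-340-5p	tumor_suppressor	true
miR-342-3p	tumor_suppressor	true
miR-363-3p	oncomiR	false
miR-370-3p	tumor_suppressor	true
miR-376a-3p	tumor_suppressor	true
miR-410-3p	tumor_suppressor	true
miR-424-5p	tumor_suppressor	true
miR-451a-5p	context_dependent	true
miR-582-5p	oncomiR	false
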