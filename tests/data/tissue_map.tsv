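omim_id	tissue	mapping_key
601494	heart	3
615829	whole_brain	3
253700	skeletal_muscle	3
208540	kidney	3
222222	liver	2
333333	heart	3
333333	liver	3
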