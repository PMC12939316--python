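# Highly conserved mature miRNAs with hsa homologs (display form, arm-exact).
let-7a-5p
let-7b-5p
let-7c-5p
let-7d-5p
let-7f-5p
let-7i-5p
miR-1-3p
miR-100-5p
miR-101-3p
miR-10a-5p
miR-10b-5p
miR-122-5p
miR-125b-5p
miR-126-3p
miR-133a-3p
miR-133b
miR-141-3p
miR-143-3p
miR-145-5p
miR-148a-3p
miR-17-5p
miR-181a-5p
miR-184
miR-191-5p
miR-192-5p
miR-199a-3p
miR-200a-3p
miR-200c-3p
miR-206
miR-21-5p
miR-22-3p
miR-223-3p
miR-23a-3p
miR-24-3p
miR-25-3p
miR-26a-5p
miR-26b-5p
miR-27b-3p
miR-29a-3p
miR-29b-3p
miR-30a-5p
miR-30c-5p
miR-30d-5p
miR-30e-5p
miR-451a
miR-92a-3p
miR-92b-3p
miR-99a-5p
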