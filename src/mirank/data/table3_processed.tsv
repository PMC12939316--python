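mirna	sources
let-7a-5p	Cooked pork fat; Cooked pork liver; Ultrasonicated milk; Skimmed powder milk; Butter; Infant formula
let-7b-5p	Ultrasonicated milk; Skimmed powder milk; Infant formula
let-7c-5p	Infant formula
let-7f-5p	Cooked pork liver; Ultrasonicated milk; Skimmed powder milk; Infant formula
miR-1-3p	Cooked lean meat (beef, pork); Cooked beef heart
miR-100-5p	Cooked beef heart
miR-10b-5p	Cooked lean beef; Cooked beef heart; Butter
miR-122-5p	Cooked pork liver; Ultrasonicated milk
miR-125b-5p	Cooked pork fat; Cooked pork liver; Ultrasonicated milk
miR-126-3p	Cooked lean beef; Cooked pork fat
miR-133a-3p	Cooked lean meat (beef, pork); Butter
miR-133b	Cooked lean pork
miR-143-3p	Cooked lean meat (beef, pork); Cooked pork fat; Cooked offal (beef heart, pork liver); Butter
miR-148a-3p	Cooked pork fat; Skimmed powder milk; Butter
miR-192-5p	Cooked pork liver
miR-200c-3p	Ultrasonicated milk; Skimmed powder milk; Infant formula
miR-206	Cooked lean meat (beef, pork)
miR-21-5p	Cooked pork fat; Ultrasonicated milk; Skimmed powder milk
miR-22-3p	Cooked lean beef; Butter
miR-23a-3p	Cooked pork fat
miR-26a-5p	Cooked lean meat (beef, pork); Cooked pork fat; Cooked offal (beef heart, pork liver); Skimmed powder milk; Butter
miR-27b-3p	Cooked lean pork; Cooked beef heart
miR-30a-5p	Cooked lean beef; Cooked offal (beef heart, pork liver); Ultrasonicated milk; Skimmed powder milk; Butter
miR-30d-5p	Ultrasonicated milk; Skimmed powder milk
miR-451a	Cooked pork liver
miR-99a-5p	Cooked lean pork; Cooked pork fat; Cooked offal (beef heart, pork liver)
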