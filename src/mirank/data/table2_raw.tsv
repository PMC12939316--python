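mirna	sources
let-7a-5p	Lean pork; Meat fat (beef, rabbit); Bovine colostrum; Milk (cow, buffalo, goat, sheep, camel); Pearl oyster
let-7b-5p	Beef fat; Bovine colostrum; Milk (cow, buffalo, goat, sheep, camel)
let-7c-5p	Meat fat (beef, buffalo); Camel milk
let-7d-5p	Lean rabbit meat
let-7f-5p	Lean pork; Meat fat (beef, buffalo); Beef liver; Bovine colostrum; Milk (goat, camel)
let-7i-5p	Rabbit meat fat
miR-1-3p	Tilapia fish; Lean meat (beef, pork, rabbit); Sheep fat; Beef heart
miR-100-5p	Offal (beef heart, beef rumen and intestines, rabbit liver); Pearl oyster
miR-101-3p	Lean rabbit meat
miR-10a-5p	Lean beef; Beef rumen and intestines
miR-10b-5p	Lean meat (beef, goat, pork); Offal (beef heart, beef rumen and intestines)
miR-122-5p	Offal (beef liver, rabbit liver)
miR-125b-5p	Meat fat (beef, sheep); Tilapia fish; Pearl oyster; Sea cucumber
miR-126-3p	Beef fat
miR-133a-3p	Lean meat (pork, rabbit); Sheep fat; Tilapia fish
miR-141-3p	Lean beef; Milk (cow, buffalo, goat)
miR-143-3p	Lean meat (beef, goat, pork); Meat fat (rabbit, buffalo); Offal (beef heart, beef liver, beef rumen and intestines)
miR-145-5p	Beef rumen and intestines
miR-148a-3p	Lean meat (beef, goat); Offal (beef liver, rabbit liver); Bovine colostrum; Milk (cow, buffalo, goat, sheep)
miR-17-5p	Tilapia fish
miR-181a-5p	Lean goat meat; Buffalo meat fat; Bovine colostrum
miR-184	Pearl oyster; Sea cucumber
miR-191-5p	Lean goat meat; Camel milk
miR-192-5p	Offal (beef liver, beef rumen and intestines)
miR-199a-3p	Beef fat; Tilapia fish
miR-200a-3p	Milk (buffalo, goat, sheep)
miR-200c-3p	Milk (cow, camel)
miR-206	Lean meat (beef, pork, rabbit); Sheep meat fat; Tilapia fish
miR-21-5p	Lean meat (beef, goat); Beef rumen and intestines; Bovine colostrum; Milk (cow, buffalo, goat, sheep)
miR-22-3p	Lean meat (beef, goat); Beef liver; Bovine colostrum; Cow milk; Tilapia fish
miR-223-3p	Goat milk
miR-24-3p	Beef rumen and intestines
miR-25-3p	Milk (buffalo, camel)
miR-26a-5p	Lean meat (beef, goat, pork); Meat fat (rabbit, sheep, buffalo); Offal (beef heart, beef liver, beef rumen and intestines); Bovine colostrum; Milk (cow, goat, sheep); Pearl oyster
miR-26b-5p	Lean rabbit meat; Sheep milk
miR-27b-3p	Lean meat (beef, rabbit); Buffalo meat fat; Offal (beef liver, beef rumen and intestines); Pearl oyster
miR-29a-3p	Sheep milk
miR-29b-3p	Camel milk
miR-30a-5p	Lean meat (beef, goat); Offal (beef heart, beef liver, beef rumen and intestines); Bovine colostrum; Milk (cow, goat, sheep)
miR-30c-5p	Sheep meat fat
miR-30d-5p	Sheep meat fat; Cow milk
miR-30e-5p	Beef heart; Pearl oyster
miR-451a	Buffalo meat fat
miR-92a-3p	Camel milk; Sea cucumber
miR-92b-3p	Sea cucumber
miR-99a-5p	Rabbit meat fat; Offal (beef heart, rabbit liver); Pearl oyster
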