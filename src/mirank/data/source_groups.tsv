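source	group	state
Lean pork	lean_meat	raw
Lean beef	lean_meat	raw
Lean rabbit meat	lean_meat	raw
Lean goat meat	lean_meat	raw
Lean meat (beef, pork, rabbit)	lean_meat	raw
Lean meat (beef, goat, pork)	lean_meat	raw
Lean meat (pork, rabbit)	lean_meat	raw
Lean meat (beef, goat)	lean_meat	raw
Lean meat (beef, rabbit)	lean_meat	raw
Beef fat	meat_fat	raw
Sheep fat	meat_fat	raw
Sheep meat fat	meat_fat	raw
Rabbit meat fat	meat_fat	raw
Buffalo meat fat	meat_fat	raw
Meat fat (beef, rabbit)	meat_fat	raw
Meat fat (beef, buffalo)	meat_fat	raw
Meat fat (beef, sheep)	meat_fat	raw
Meat fat (rabbit, buffalo)	meat_fat	raw
Meat fat (rabbit, sheep, buffalo)	meat_fat	raw
Beef liver	meat_offal	raw
Beef heart	meat_offal	raw
Beef rumen and intestines	meat_offal	raw
Offal (beef heart, beef rumen and intestines, rabbit liver)	meat_offal	raw
Offal (beef heart, beef rumen and intestines)	meat_offal	raw
Offal (beef liver, rabbit liver)	meat_offal	raw
Offal (beef liver, beef rumen and intestines)	meat_offal	raw
Offal (beef heart, beef liver, beef rumen and intestines)	meat_offal	raw
Offal (beef heart, rabbit liver)	meat_offal	raw
Bovine colostrum	dairy	raw
Cow milk	dairy	raw
Goat milk	dairy	raw
Sheep milk	dairy	raw
Camel milk	dairy	raw
Milk (cow, buffalo, goat, sheep, camel)	dairy	raw
Milk (goat, camel)	dairy	raw
Milk (cow, buffalo, goat)	dairy	raw
Milk (cow, buffalo, goat, sheep)	dairy	raw
Milk (buffalo, goat, sheep)	dairy	raw
Milk (cow, camel)	dairy	raw
Milk (buffalo, camel)	dairy	raw
Milk (cow, goat, sheep)	dairy	raw
Tilapia fish	seafood	raw
Pearl oyster	seafood	raw
Sea cucumber	seafood	raw
Cooked lean beef	lean_meat	processed
Cooked lean pork	lean_meat	processed
Cooked lean meat (beef, pork)	lean_meat	processed
Cooked pork fat	meat_fat	processed
Cooked pork liver	meat_offal	processed
Cooked beef heart	meat_offal	processed
Cooked offal (beef heart, pork liver)	meat_offal	processed
Ultrasonicated milk	dairy	processed
Skimmed powder milk	dairy	processed
Butter	dairy	processed
Infant formula	dairy	processed
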