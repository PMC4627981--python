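evc_code,evc_name,min_tfi,max_tfi,fuel_type
68,Creekline grassy woodland,20,150,7
71,Hills herb-rich woodland,15,150,7
164,Creekline herb-rich woodland,15,150,7
175,Grassy woodland,5,45,7
177,Valley slopes dry forest,10,100,7
198,Sedgy riparian woodland,20,85,7
894,Scoria cone woodland,4,15,7
30,Wet forest,45,300,9
201,Shrubby wet forest,25,150,9
18,Riparian forest,10,80,10
83,Swampy riparian woodland,15,125,10
17,Riparian scrub or swampy riparian woodland complex,10,80,11
233,Wet sands thicket,15,90,11
851,Stream bank shrubland,15,90,11
31,Cool temperate rainforest,45,999,1
8,Wet heathland,12,45,13
165,Damp heath scrub,10,90,13
836,Damp heath scrub/heathy woodland complex,10,90,13
6,Sand heathland,8,45,14
7,Clay heathland,10,45,14
1,Coastal dune scrub or coastal dune grassland mosaic,10,90,1
161,Coastal headland scrub,8,90,1
162,Coastal headland scrub/coastal tussock grassland mosaic,8,90,1
181,Coast gully thicket,10,90,1
858,Coastal alkaline scrub,10,70,1
302,Coastal saltmarsh/mangrove shrubland mosaic,8,90,2
163,Coastal tussock grassland,5,40,3
48,Heathy woodland,5,45,4
282,Shrubby woodland,10,45,4
16,Lowland forest,8,80,5
20,Heathy dry forest,10,45,5
21,Shrubby dry forest,5,45,5
22,Grassy dry forest,5,45,6
23,Herb rich foothill forest,8,90,6
45,Shrubby foothill forest,8,90,6
178,Herb-rich foothill forest/shrubby foothill forest complex,8,90,6
3,Damp sands herb rich woodland,10,90,7
47,Valley grassy forest,10,100,7
55,Plains grassy woodland,4,15,7
67,Alluvial terraces herb-rich woodland,4,15,7
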