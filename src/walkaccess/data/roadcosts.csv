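category,speed
motorway,5.0
motorway_link,5.0
trunk,5.0
trunk_link,5.0
primary,5.0
primary_link,5.0
secondary,4.5
secondary_link,4.5
tertiary,4.5
tertiary_link,4.5
residential,4.0
living_street,4.0
pedestrian,4.0
unclassified,3.5
track,3.5
track_grade1,3.5
track_grade2,3.5
track_grade3,3.5
track_grade4,3.5
track_grade5,3.5
service,3.5
bridleway,3.5
cycleway,3.5
path,3.5
footway,3.5
steps,3.5
unknown,3.5
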