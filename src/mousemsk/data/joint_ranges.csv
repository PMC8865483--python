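# Skeletal segment grouping, joints and per-DoF ranges of motion (degrees).
# One row per DoF.  "count" is the number of serial bones of that name
# (e.g. 13 thoracic vertebrae each carry the listed DoFs).
# Transcription repairs (note column):
#   range-repair: ankle plantarflexion-dorsiflexion printed "[-50.0, -50.0]"
#     recorded as [-50.0, 50.0]; metatarsophalangeal extension-flexion printed
#     "[-5.0, -5.0]" recorded as [-5.0, 5.0] (a min==max range is degenerate).
#   count-repair: thoracic printed "{1-6}" but the digitization text counts 13
#     thoracic bones; cervical printed "{1-6}" but the text counts 8.
#   name-repair: "extemal-intemal" -> "external-internal".
group,bone,count,joint,dof,range_min_deg,range_max_deg,model_species,note
hindlimb,Femur,1,Hip,extension-flexion,-30.0,50.0,mouse,
hindlimb,Femur,1,Hip,abduction-adduction,-40.0,20.0,rat,
hindlimb,Femur,1,Hip,external-internal rotation,-10.0,30.0,rat,name-repair
hindlimb,Tibia,1,Knee,flexion-extension,-145.0,-40.0,mouse,
hindlimb,Tarsus,1,Ankle,plantarflexion-dorsiflexion,-50.0,50.0,mouse,range-repair
hindlimb,Tarsus,1,Ankle,inversion-eversion,-30.0,50.0,rat,
hindlimb,Tarsus,1,Ankle,abduction-adduction,-10.0,30.0,rat,
hindlimb,Metatarsus,5,MTP,extension-flexion,-5.0,5.0,,range-repair
hindlimb,Phalange,5,Phalange,extension-flexion,-5.0,5.0,,
forelimb,Humerus,1,Shoulder,retraction-protraction,-45.0,45.0,,
forelimb,Humerus,1,Shoulder,abduction-adduction,-36.0,3.0,rat,
forelimb,Humerus,1,Shoulder,external-internal rotation,-40.0,14.0,rat,name-repair
forelimb,Ulna,1,Elbow,extension-flexion,60.0,153.0,rat,
forelimb,Radius,1,Elbow,supination-pronation,-5.0,30.0,rat,
forelimb,Carpus,1,Wrist,extension-flexion,-20.0,50.0,rat,
forelimb,Carpus,1,Wrist,abduction-adduction,-10.0,10.0,,
forelimb,Metacarpus,5,MTC,extension-flexion,-5.0,5.0,,
forelimb,Phalange,5,Phalange,extension-flexion,-5.0,5.0,,
spine,Lumbar,6,Lumbar,flexion-extension,-6.0,6.0,mouse,
spine,Lumbar,6,Lumbar,lateral bending,-5.0,5.0,,
spine,Thoracic,13,Thoracic,flexion-extension,-5.0,5.0,mouse,count-repair
spine,Thoracic,13,Thoracic,lateral bending,-5.0,5.0,,count-repair
spine,Cervical,8,Cervical,flexion-extension,-9.0,9.0,mouse,count-repair
spine,Cervical,8,Cervical,lateral bending,-5.0,5.0,,count-repair
head,Upper jaw,1,Head,flexion-extension,-50.0,50.0,,
head,Lower jaw,1,Jaw,flexion-extension,0.0,30.0,,
tail,Tail,23,Tail,flexion-extension,-10.0,10.0,,
tail,Tail,23,Tail,lateral bending,-10.0,10.0,,
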