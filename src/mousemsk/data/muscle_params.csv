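# Hindlimb and forelimb muscle parameter sets (59 muscle-tendon units).
# Columns: section, group (joints spanned), full name, abbreviation,
#   f_max_N (Fm0), l_opt_mm (lmo), l_slack_mm (lts), alpha_opt_deg (alpha_o),
#   ratio (printed lts/lmo, 2 decimals), note.
# Transcription notes: names "Obturator extemus" -> "Obturator externus" and
#   "Peroneus digit! quarti" -> "Peroneus digiti quarti" repair obvious OCR
#   defects; numeric cells are never altered.  note=ratio-mismatch marks rows
#   whose printed ratio differs from l_slack/l_opt by more than 0.005 (up to
#   0.0064) in the source table itself.
section,group,name,abbreviation,f_max_N,l_opt_mm,l_slack_mm,alpha_opt_deg,ratio,note
hindlimb,Hip,Adductor brevis,AB,0.23,9.5,2.66,0.0,0.28,
hindlimb,Hip,Adductor longus,AL,0.4,11.9,4.15,0.0,0.35,
hindlimb,Hip,Adductor magnus,AM,0.61,12.2,4.85,0.0,0.4,
hindlimb,Hip,Biceps femoris anterior,BFA,0.88,17.84,5.97,0.0,0.33,
hindlimb,Hip,Caudofemoralis,CF,0.55,17.85,4.82,0.0,0.27,
hindlimb,Hip,Gemellus,GEM,0.18,3.33,0.02,0.0,0.01,
hindlimb,Hip,Gluteus maximus (dorsal),GM(dr),0.94,14.99,5.75,20.42,0.38,
hindlimb,Hip,Gluteus maximus (mid),GM(mi),1.03,14.28,5.5,20.42,0.38,ratio-mismatch
hindlimb,Hip,Gluteus maximus (ventral),GM(ve),1.05,14.59,5.61,20.42,0.38,
hindlimb,Hip,Iliacus,ILI,0.55,9.67,3.1,0.0,0.32,
hindlimb,Hip,Obturator externus,OE,0.09,4.37,1.71,0.0,0.39,ocr-name-repair
hindlimb,Hip,Obturator internus,OI,0.31,6.3,0.72,0.0,0.12,ratio-mismatch
hindlimb,Hip,Pectineus,PECT,0.36,4.27,2.79,15.18,0.65,
hindlimb,Hip,Psoas major,PMA,1.34,8.01,5.76,15.54,0.72,
hindlimb,Hip,Psoas minor,PMI,1.09,6.79,4.58,12.57,0.67,
hindlimb,Hip,Quadratus femoris,QF,2.03,4.99,1.18,0.0,0.24,
hindlimb,Hip-Knee,Biceps femoris posterior (cranial),BFP(cr),0.72,16.46,8.02,0.0,0.49,
hindlimb,Hip-Knee,Biceps femoris posterior (mid),BFP(mi),0.73,16.9,8.08,0.0,0.48,
hindlimb,Hip-Knee,Biceps femoris posterior (caudal),BFP(ca),0.61,19.81,6.72,0.0,0.34,
hindlimb,Hip-Knee,Gracilis anterior,GA,0.4,14.76,10.16,0.0,0.69,
hindlimb,Hip-Knee,Gracilis posterior,GP,0.34,15.92,7.68,0.0,0.48,
hindlimb,Hip-Knee,Rectus femoris,RF,4.16,9.87,15.77,15.89,1.6,
hindlimb,Hip-Knee,Semimembranosus,SM,1.92,20.14,7.07,0.0,0.35,
hindlimb,Hip-Knee,Semitendinosus,ST,1.3,19.1,8.25,0.0,0.43,
hindlimb,Knee,Popliteus,POP,0.31,3.3,3.26,0.0,0.99,
hindlimb,Knee,Vastus intermedius,VI,0.37,10.08,11.68,10.92,1.16,
hindlimb,Knee,Vastus lateralis,VL,2.83,11.18,12.07,15.53,1.08,
hindlimb,Knee,Vastus medialis,VM,1.1,10.77,12.67,16.15,1.18,
hindlimb,Ankle-Knee,Lateral gastrocnemius,LG,3.78,6.97,17.89,17.28,2.57,
hindlimb,Ankle-Knee,Medial gastrocnemius,MG,1.75,7.29,18.5,14.24,2.54,
hindlimb,Ankle-Knee,Plantaris,PLANT,0.88,5.75,20.23,17.1,3.52,
hindlimb,Ankle,Extensor digitorum longus,EDL,0.37,8.12,30.42,12.39,3.74,ratio-mismatch
hindlimb,Ankle,Extensor hallucis longus,EHL,0.07,7.71,23.32,9.56,3.02,
hindlimb,Ankle,Flexor digitorum longus,FDL,1.9,5.71,36.6,15.2,6.41,
hindlimb,Ankle,Peroneus brevis,PB,0.4,3.04,13.33,11.46,4.39,ratio-mismatch
hindlimb,Ankle,Peroneus digiti quarti,PDQA,0.11,5.05,30.31,12.42,6.0,ocr-name-repair
hindlimb,Ankle,Peroneus digiti quinti,PDQI,0.1,4.72,25.53,9.44,5.41,
hindlimb,Ankle,Peroneus longus,PL,0.65,5.21,19.4,14.9,3.72,
hindlimb,Ankle,Peroneus tertius,PT,0.46,4.78,15.81,12.46,3.31,
hindlimb,Ankle,Soleus,SOL,0.59,4.5,10.53,11.43,2.34,
hindlimb,Ankle,Tibialis anterior,TA,2.42,6.61,15.92,16.58,2.41,
hindlimb,Ankle,Tibialis posterior,TP,0.55,4.72,19.71,15.44,4.18,
forelimb,Shoulder,Coracobrachialis,COR,0.28,5.18,4.64,13.85,0.9,
forelimb,Elbow-Shoulder,Biceps brachii long head,BBL,0.78,11.63,7.52,21.68,0.65,
forelimb,Elbow-Shoulder,Triceps brachii lateral head,TBL,0.71,8.17,4.53,23.41,0.55,
forelimb,Elbow,Anconeus,AN,0.15,1.42,1.49,24.65,1.05,
forelimb,Elbow,Biceps brachii short head,BBS,0.84,9.08,6.07,28.27,0.67,
forelimb,Elbow,Brachialis,BRA,0.25,10.06,5.58,9.89,0.56,ratio-mismatch
forelimb,Elbow,Pronator teres,PTE,0.55,2.75,4.96,26.17,1.81,ratio-mismatch
forelimb,Elbow,Triceps brachii medial head,TBM,0.45,4.93,6.43,30.33,1.3,
forelimb,Elbow,Triceps brachii long head,TBO,4.65,7.01,4.88,41.88,0.7,
forelimb,Elbow-Wrist,Extensor carpi radialis brevis,ECRB,0.35,14.45,7.71,29.49,0.53,
forelimb,Elbow-Wrist,Extensor carpi radialis longus,ECRL,0.38,13.86,7.29,26.4,0.53,
forelimb,Elbow-Wrist,Extensor carpi ulnaris,ECU,0.52,7.67,10.84,20.8,1.41,
forelimb,Elbow-Wrist,Extensor indicis proprius 1,EIP1,0.07,5.05,2.99,19.0,0.59,
forelimb,Elbow-Wrist,Extensor indicis proprius 2,EIP2,0.07,5.27,3.3,19.0,0.63,
forelimb,Elbow-Wrist,Flexor carpi radialis,FCR,0.38,8.92,10.74,15.02,1.2,
forelimb,Elbow-Wrist,Flexor carpi ulnaris,FCU,0.69,8.28,10.29,20.95,1.24,
forelimb,Elbow-Wrist,Palmaris longus,PLO,0.27,10.9,9.12,24.65,0.84,
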