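slide_id,reference,index_call,comparator_call
T001,malignant,positive,malignant_suspicious
T002,malignant,positive,malignant_suspicious
T003,malignant,positive,malignant_suspicious
T004,malignant,positive,malignant_suspicious
T005,malignant,positive,malignant_suspicious
T006,malignant,positive,malignant_suspicious
T007,malignant,positive,malignant_suspicious
T008,malignant,positive,malignant_suspicious
T009,malignant,positive,malignant_suspicious
T010,malignant,positive,malignant_suspicious
T011,malignant,positive,malignant_suspicious
T012,malignant,positive,malignant_suspicious
T013,malignant,positive,malignant_suspicious
T014,malignant,positive,malignant_suspicious
T015,malignant,positive,malignant_suspicious
T016,malignant,positive,malignant_suspicious
T017,malignant,positive,malignant_suspicious
T018,malignant,positive,malignant_suspicious
T019,malignant,positive,malignant_suspicious
T020,malignant,positive,malignant_suspicious
T021,malignant,positive,malignant_suspicious
T022,malignant,positive,malignant_suspicious
T023,malignant,positive,malignant_suspicious
T024,malignant,positive,malignant_suspicious
T025,malignant,positive,malignant_suspicious
T026,malignant,positive,malignant_suspicious
T027,malignant,positive,malignant_suspicious
T028,malignant,positive,malignant_suspicious
T029,malignant,positive,malignant_suspicious
T030,malignant,positive,malignant_suspicious
T031,malignant,positive,malignant_suspicious
T032,malignant,positive,malignant_suspicious
T033,malignant,positive,malignant_suspicious
T034,malignant,positive,malignant_suspicious
T035,malignant,positive,malignant_suspicious
T036,malignant,positive,malignant_suspicious
T037,malignant,positive,malignant_suspicious
T038,malignant,positive,malignant_suspicious
T039,malignant,positive,malignant_suspicious
T040,malignant,positive,malignant_suspicious
T041,malignant,positive,malignant_suspicious
T042,malignant,positive,malignant_suspicious
T043,malignant,positive,malignant_suspicious
T044,malignant,positive,malignant_suspicious
T045,malignant,positive,malignant_suspicious
T046,malignant,positive,malignant_suspicious
T047,malignant,positive,malignant_suspicious
T048,malignant,positive,malignant_suspicious
T049,malignant,positive,malignant_suspicious
T050,malignant,positive,malignant_suspicious
T051,malignant,positive,malignant_suspicious
T052,malignant,positive,malignant_suspicious
T053,malignant,positive,malignant_suspicious
T054,malignant,positive,malignant_suspicious
T055,malignant,positive,malignant_suspicious
T056,malignant,positive,malignant_suspicious
T057,malignant,positive,malignant_suspicious
T058,malignant,positive,malignant_suspicious
T059,malignant,negative,malignant_suspicious
T060,malignant,negative,malignant_suspicious
T061,malignant,negative,malignant_suspicious
T062,malignant,negative,benign
T063,malignant,negative,inadequate
T064,benign_normal,positive,malignant_suspicious
T065,benign_normal,positive,malignant_suspicious
T066,benign_normal,negative,malignant_suspicious
T067,benign_normal,negative,malignant_suspicious
T068,benign_normal,negative,malignant_suspicious
T069,benign_normal,negative,malignant_suspicious
T070,benign_normal,negative,atypical
T071,benign_normal,negative,atypical
T072,benign_normal,negative,benign
T073,benign_normal,negative,benign
T074,benign_normal,negative,benign
T075,benign_normal,negative,benign
T076,benign_normal,negative,benign
T077,benign_normal,negative,benign
T078,benign_normal,negative,benign
T079,benign_normal,negative,benign
T080,benign_normal,negative,benign
T081,benign_normal,negative,benign
T082,benign_normal,negative,benign
T083,benign_normal,negative,benign
T084,benign_normal,negative,benign
T085,benign_normal,negative,benign
T086,benign_normal,negative,benign
T087,benign_normal,negative,benign
T088,benign_normal,negative,benign
T089,benign_normal,negative,benign
T090,benign_normal,negative,benign
T091,benign_normal,negative,benign
T092,benign_normal,negative,benign
T093,benign_normal,negative,benign
T094,benign_normal,negative,benign
T095,benign_normal,negative,benign
T096,benign_normal,negative,benign
T097,benign_normal,negative,benign
T098,benign_normal,negative,benign
T099,benign_normal,negative,benign
T100,benign_normal,negative,benign
T101,benign_normal,negative,benign
T102,benign_normal,negative,benign
T103,benign_normal,negative,benign
T104,benign_normal,negative,benign
T105,benign_normal,negative,benign
T106,benign_normal,negative,benign
T107,benign_normal,negative,benign
T108,benign_normal,negative,benign
T109,benign_normal,negative,benign
T110,benign_normal,negative,benign
T111,benign_normal,negative,benign
T112,benign_normal,negative,benign
T113,benign_normal,negative,benign
T114,benign_normal,negative,benign
T115,benign_normal,negative,benign
T116,benign_normal,negative,benign
T117,benign_normal,negative,benign
T118,benign_normal,negative,benign
T119,benign_normal,negative,benign
T120,benign_normal,negative,benign
T121,benign_normal,negative,benign
T122,benign_normal,negative,benign
T123,benign_normal,negative,inadequate
T124,benign_normal,negative,inadequate
T125,benign_normal,negative,inadequate
T126,benign_normal,negative,inadequate
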