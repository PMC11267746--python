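Santiago
Agustín
Benjamín
Vicente
Martín
Matías
Joaquín
Tomás
Gaspar
Lucas
Maximiliano
Alonso
Diego
José
Juan
Luis
Carlos
Jorge
Francisco
Manuel
Víctor
Héctor
Pedro
Sergio
Mario
Roberto
Fernando
Patricio
Cristián
Mauricio
Rodrigo
Marcelo
Claudio
Andrés
Felipe
Pablo
Gonzalo
Ricardo
Eduardo
Óscar
Raúl
Hugo
Alejandro
Daniel
Miguel
Antonio
Ramón
Alberto
Guillermo
Enrique
Arturo
Rafael
Emilio
Ernesto
Julio
César
Rubén
Iván
Esteban
Nicolás
Sebastián
Ignacio
Camilo
Javier
Álvaro
Cristóbal
Renato
Bruno
Dante
Franco
Gabriel
Samuel
David
Elías
Simón
Amaro
Borja
Clemente
Domingo
Facundo
Bastián
Brayan
Kevin
Yerko
Marco
Italo
Hernán
Osvaldo
Rolando
Waldo
Exequiel
Abraham
Moisés
Israel
Jaime
Leonardo
Mateo
Máximo
Salvador
Aníbal
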